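"""Set-to-set topological proximity and its empirical null.

The distance between two protein sets A and B on a map is the average-min
("modified Hausdorff") jump distance: for every protein in A take the jump
count to the closest protein of B, likewise from B to A, and average the
directed minima.  Two averaging conventions are computed:

* ``pooled_mean`` — one mean over all |A|+|B| directed minima (the headline
  statistic reported by default);
* ``mean_of_means`` — the mean of the two directed means, which weights the
  two sets equally regardless of their sizes.

The classical max-min Hausdorff distance is carried as a diagnostic field
(``hausdorff_max``) but plays no role in the analysis.

Significance of an observed distance is assessed against the empirical
distribution of the same statistic over all unordered pairs of conditions
in a condition database (an all-pairs null), via its ECDF.  A normal fit
(mean, sd) of the null is reported alongside for descriptive comparison
only; the ECDF is the primary, distribution-free reference.

Proteins absent from the map's largest connected component are dropped
(and counted) before any distance is computed — an unreachable protein has
no defined jump distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .conditions import Condition, Motive
from .graph import CellMap, bfs_jumps, largest_component

logger = logging.getLogger(__name__)

#: SetDistance fields selectable as the null/report statistic.
STATISTICS = ("pooled_mean", "mean_of_means", "min_pairwise")


@dataclass
class SetDistance:
    """Directed-min jump statistics between two protein sets on a map."""

    forward_mean: float  # mean over A of min jumps to B
    reverse_mean: float  # mean over B of min jumps to A
    pooled_mean: float  # mean of all |A|+|B| directed minima
    mean_of_means: float  # (forward_mean + reverse_mean) / 2
    min_pairwise: int  # smallest jump count between any a in A, b in B
    hausdorff_max: int  # classical max-min Hausdorff (diagnostic)
    n_dropped: int  # proteins excluded as absent/unreachable
    n_a: int  # |A| used (after dropping)
    n_b: int  # |B| used (after dropping)

    def __getitem__(self, stat: str) -> float:
        if stat not in STATISTICS and stat not in ("forward_mean", "reverse_mean"):
            raise KeyError(f"unknown statistic {stat!r}")
        return getattr(self, stat)


def _restrict(ids: set[str], component: set[str]) -> set[str]:
    return ids & component


def set_distance(cell_map: CellMap, a: Iterable[str], b: Iterable[str]) -> SetDistance:
    """Average-min jump distance between protein sets ``a`` and ``b``.

    Proteins outside the map's largest connected component are dropped and
    counted in ``n_dropped``; if either set is emptied by the restriction
    a ``ValueError("no representatives in map")`` is raised.
    """
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("empty node set")
    component = largest_component(cell_map)
    comp_ids = component.node_ids
    a_in, b_in = _restrict(a, comp_ids), _restrict(b, comp_ids)
    n_dropped = (len(a) - len(a_in)) + (len(b) - len(b_in))
    if not a_in or not b_in:
        raise ValueError("no representatives in map")
    d_to_b = bfs_jumps(component, b_in)  # jump count to nearest member of B
    d_to_a = bfs_jumps(component, a_in)
    fwd = [d_to_b[x] for x in sorted(a_in)]
    rev = [d_to_a[x] for x in sorted(b_in)]
    forward_mean = math.fsum(fwd) / len(fwd)
    reverse_mean = math.fsum(rev) / len(rev)
    return SetDistance(
        forward_mean=forward_mean,
        reverse_mean=reverse_mean,
        pooled_mean=math.fsum(fwd + rev) / (len(fwd) + len(rev)),
        mean_of_means=(forward_mean + reverse_mean) / 2.0,
        min_pairwise=min(min(fwd), min(rev)),
        hausdorff_max=max(max(fwd), max(rev)),
        n_dropped=n_dropped,
        n_a=len(a_in),
        n_b=len(b_in),
    )


@dataclass
class NullDistribution:
    """All-pairs condition distances: values, moments and an ECDF.

    ``mean``/``sd`` are the sample mean and sample standard deviation
    (ddof=1) of ``values``; the ECDF uses the closed comparison
    P(X <= d).
    """

    values: np.ndarray
    pairs: list[tuple[str, str]]
    statistic: str
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self._sorted = np.sort(self.values)

    @property
    def n_comparisons(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        if len(self.values) < 2:
            return 0.0
        return float(np.std(self.values, ddof=1))

    def ecdf(self, d: float) -> float:
        """Empirical P(value <= d)."""
        return float(np.searchsorted(self._sorted, d, side="right")) / len(self._sorted)

    def normal_cdf(self, d: float) -> float:
        """Tail probability under a normal fitted to (mean, sd) — descriptive."""
        from scipy.stats import norm

        if self.sd == 0:
            return float(d >= self.mean)
        return float(norm.cdf(d, loc=self.mean, scale=self.sd))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_a": [p[0] for p in self.pairs],
                "condition_b": [p[1] for p in self.pairs],
                self.statistic: self.values,
            }
        )


def _component_distance_index(
    cell_map: CellMap, named_sets: Sequence[tuple[str, set[str]]]
) -> tuple[dict[str, set[str]], dict[str, dict[str, int]], list[str]]:
    """Restrict each named set to the largest component and precompute, for
    each set, the jump distance from every component node to its nearest
    member (one multi-source BFS per set)."""
    component = largest_component(cell_map)
    comp_ids = component.node_ids
    usable: dict[str, set[str]] = {}
    dist: dict[str, dict[str, int]] = {}
    skipped: list[str] = []
    for name, ids in named_sets:
        in_comp = set(ids) & comp_ids
        if not in_comp:
            skipped.append(name)
            continue
        usable[name] = in_comp
        dist[name] = bfs_jumps(component, in_comp)
    if skipped:
        logger.warning("skipped %d set(s) with no in-map representative: %s",
                       len(skipped), ", ".join(skipped[:5]))
    return usable, dist, skipped


def _pair_statistics(members_a, members_b, d_to_b, d_to_a) -> SetDistance:
    fwd = [d_to_b[x] for x in sorted(members_a)]
    rev = [d_to_a[x] for x in sorted(members_b)]
    forward_mean = math.fsum(fwd) / len(fwd)
    reverse_mean = math.fsum(rev) / len(rev)
    return SetDistance(
        forward_mean,
        reverse_mean,
        math.fsum(fwd + rev) / (len(fwd) + len(rev)),
        (forward_mean + reverse_mean) / 2.0,
        min(min(fwd), min(rev)),
        max(max(fwd), max(rev)),
        n_dropped=0,
        n_a=len(fwd),
        n_b=len(rev),
    )


def null_distribution(
    cell_map: CellMap, conditions: Sequence[Condition], statistic: str = "pooled_mean"
) -> NullDistribution:
    """Distances over all unordered pairs of conditions (the empirical null).

    Conditions with no effector in the map's largest component are skipped
    with a warning; for the k usable conditions exactly C(k, 2) comparisons
    are made.  One multi-source BFS per usable condition makes the all-pairs
    sweep linear in k rather than quadratic.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    named = [(c.name, c.effectors) for c in conditions]
    usable, dist, skipped = _component_distance_index(cell_map, named)
    names = [n for n, _ in named if n in usable]
    if len(names) < 2:
        raise ValueError("need >= 2 conditions with effectors in the map")
    pairs, values = [], []
    for na, nb in combinations(names, 2):
        sd = _pair_statistics(usable[na], usable[nb], dist[nb], dist[na])
        pairs.append((na, nb))
        values.append(sd[statistic])
    return NullDistribution(np.asarray(values, float), pairs, statistic, skipped)


def anchored_null(
    cell_map: CellMap,
    anchor: Iterable[str],
    conditions: Sequence[Condition],
    statistic: str = "pooled_mean",
    anchor_name: str = "anchor",
) -> NullDistribution:
    """Distances from one fixed anchor set to every condition.

    The anchor-vs-all-conditions reference distribution: one value per
    usable condition.  This is the calibrated null for judging how close a
    *particular* set (a seed list, a pathway) lies to one condition —
    against it, the percentiles of the conditions themselves are uniform by
    construction, whereas against the all-pairs null they need not be,
    because every comparison then shares the same anchor.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    anchor = set(anchor)
    if not anchor:
        raise ValueError("empty node set")
    named = [(c.name, c.effectors) for c in conditions]
    usable, dist, skipped = _component_distance_index(cell_map, named)
    names = [n for n, _ in named if n in usable]
    if not names:
        raise ValueError("no condition has effectors in the map")
    component = largest_component(cell_map)
    anchor_in = anchor & component.node_ids
    if not anchor_in:
        raise ValueError("no representatives in map")
    d_to_anchor = bfs_jumps(component, anchor_in)
    pairs, values = [], []
    for name in names:
        sd = _pair_statistics(anchor_in, usable[name], dist[name], d_to_anchor)
        pairs.append((anchor_name, name))
        values.append(sd[statistic])
    return NullDistribution(np.asarray(values, float), pairs, statistic, skipped)


def percentile_of(null: NullDistribution, d: float, kind: str = "empirical") -> float:
    """Fraction of null comparisons at distance <= d.

    ``kind="empirical"`` (default) uses the ECDF with the closed comparison;
    ``kind="normal"`` uses the CDF of a normal fitted to the null's
    (mean, sd), for descriptive comparison with the empirical value.
    """
    if null.n_comparisons == 0:
        raise ValueError("empty null distribution")
    if kind == "empirical":
        return null.ecdf(d)
    if kind == "normal":
        return null.normal_cdf(d)
    raise ValueError(f"unknown kind {kind!r}")


def pathway_to_motive_distances(
    cell_map: CellMap,
    seed_pathway_sets: dict[str, set[str]],
    motives: Sequence[Motive],
) -> pd.DataFrame:
    """Distance table: one row per (pathway set, motive) pair.

    Columns: pathway, motive, pooled_mean, mean_of_means, min_pairwise,
    n_dropped.  The report-level analogue of a pathway-vs-mechanism
    distance matrix.
    """
    rows = []
    for pname, pset in seed_pathway_sets.items():
        for m in motives:
            sd = set_distance(cell_map, pset, m.effectors)
            rows.append(
                {
                    "pathway": pname,
                    "motive": m.name,
                    "pooled_mean": sd.pooled_mean,
                    "mean_of_means": sd.mean_of_means,
                    "min_pairwise": sd.min_pairwise,
                    "n_dropped": sd.n_dropped,
                }
            )
    return pd.DataFrame(rows)
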