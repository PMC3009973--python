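"""Protein-level link enumeration between seed and effector sets.

``direct_links`` enumerates the 1-jump relationships: every map edge with
one endpoint among the effectors and the other among the seeds.
``k_jump_links`` generalises to effector-seed pairs within k jumps,
annotated with the jump count.  ``motive_breakdown`` splits direct links by
the pathophysiological motive of the effector involved (floor percentages,
an effector belonging to several motives counted once per motive and
flagged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .conditions import Motive
from .graph import CellMap

logger = logging.getLogger(__name__)


@dataclass
class LinkReport:
    """Direct and k-jump relationships between an effector and a seed set."""

    direct_edges: list[tuple[str, str, frozenset]] = field(default_factory=list)
    k_jump_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    k: int | None = None

    @property
    def n_direct(self) -> int:
        return len(self.direct_edges)

    @property
    def n_effectors_involved(self) -> int:
        return len({e for e, _, _ in self.direct_edges})

    @property
    def n_seeds_involved(self) -> int:
        return len({s for _, s, _ in self.direct_edges})

    @property
    def n_relationships(self) -> int:
        return len(self.k_jump_pairs)

    def to_frame(self) -> pd.DataFrame:
        if self.k_jump_pairs:
            return pd.DataFrame(self.k_jump_pairs, columns=["effector", "seed", "jumps"])
        return pd.DataFrame(
            [(e, s, "+".join(sorted(t))) for e, s, t in self.direct_edges],
            columns=["effector", "seed", "types"],
        )


def direct_links(cell_map: CellMap, seeds: Iterable[str], effectors: Iterable[str]) -> LinkReport:
    """All 1-jump (direct) edges between the effector and seed sets.

    Each qualifying map edge contributes one record ``(effector, seed,
    types)``.  A protein present in both sets participates from either
    side; an edge whose two endpoints are each in both sets is recorded
    once, oriented with the lexicographically smaller id as the effector.
    Records are sorted by (effector, seed).
    """
    seeds, effectors = set(seeds), set(effectors)
    if not seeds or not effectors:
        raise ValueError("empty node set")
    records = []
    for a, b, data in cell_map.graph.edges(data=True):
        a_eff, b_eff = a in effectors, b in effectors
        a_seed, b_seed = a in seeds, b in seeds
        if a_eff and b_seed and b_eff and a_seed:
            e, s = (a, b) if a <= b else (b, a)
        elif a_eff and b_seed:
            e, s = a, b
        elif b_eff and a_seed:
            e, s = b, a
        else:
            continue
        records.append((e, s, data["types"]))
    records.sort(key=lambda r: (r[0], r[1]))
    return LinkReport(direct_edges=records, k=1)


def k_jump_links(
    cell_map: CellMap, seeds: Iterable[str], effectors: Iterable[str], k: int = 2
) -> LinkReport:
    """All effector-seed pairs within k jumps, annotated with the distance.

    Pairs at distance 1 coincide exactly with the endpoint pairs of
    ``direct_links``.  A protein in both sets pairs with itself at
    distance 0; such pairs are excluded (a relationship needs at least one
    jump).  Unreachable pairs are simply absent.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seeds, effectors = set(seeds), set(effectors)
    if not seeds or not effectors:
        raise ValueError("empty node set")
    g = cell_map.graph
    pairs = []
    for e in sorted(effectors & set(g.nodes)):
        dist = nx.single_source_shortest_path_length(g, e, cutoff=k)
        for s in sorted(seeds):
            d = dist.get(s)
            if d is not None and 1 <= d <= k:
                pairs.append((e, s, d))
    report = direct_links(cell_map, seeds, effectors)
    report.k_jump_pairs = pairs
    report.k = k
    return report


def motive_breakdown(report: LinkReport, motives: Sequence[Motive]) -> pd.DataFrame:
    """Per-motive direct-link counts and floor percentages of n_direct.

    An effector belonging to several motives contributes its links once per
    motive (flagged in the ``multi_motive`` column); effectors in no motive
    are bucketed under ``"unassigned"`` with a warning.
    """
    n_direct = report.n_direct
    membership: dict[str, list[str]] = {}
    for m in motives:
        for e in m.effectors:
            membership.setdefault(e, []).append(m.name)
    rows: dict[str, dict] = {}
    for e, _, _ in report.direct_edges:
        names = membership.get(e)
        if names is None:
            logger.warning("effector %r belongs to no motive; bucketed as unassigned", e)
            names = ["unassigned"]
        for name in names:
            row = rows.setdefault(
                name, {"motive": name, "n_direct": 0, "multi_motive": False}
            )
            row["n_direct"] += 1
            if len(names) > 1:
                row["multi_motive"] = True
    out = []
    for name in sorted(rows):
        row = rows[name]
        row["pct"] = (100 * row["n_direct"]) // n_direct if n_direct else 0
        out.append(row)
    return pd.DataFrame(out, columns=["motive", "n_direct", "pct", "multi_motive"])
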