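"""Synthetic relationship universes, seed sets and condition databases.

Real inputs to this analysis — curated interaction/pathway snapshots and a
proprietary database of characterised conditions — are not redistributable,
so every stage is exercised against generated stand-ins that reproduce the
*statistical* structure the analysis assumes:

* a sparse, heavy-tailed relationship universe (preferential attachment by
  default, Erdos-Renyi available for oracle simplicity in tests), with
  per-edge relation types drawn from a configurable mix;
* seed sets of configurable size drawn from the universe;
* a condition database of ~160 conditions whose effector sets (tens of
  proteins, split over 1-3 motives) are uniform draws from the universe —
  except for an optional *planted* condition whose effectors are drawn
  from within one jump of a target seed set, giving it a known, low
  topological distance to the seeds that the proximity machinery should
  recover.

All generators are bit-reproducible from their spec + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .builder import RelationStore
from .conditions import Condition, Motive, write_condition_db
from .graph import RELATION_TYPES, CellMap

_ID_WIDTH = 6


def _protein_id(i: int) -> str:
    return f"P{i:0{_ID_WIDTH}d}"


@dataclass
class UniverseSpec:
    """Parameters of a synthetic relationship universe.

    ``attachment`` is the number of edges each new node brings in the
    preferential-attachment (Barabasi-Albert) model; ``type_mix`` gives the
    sampling probabilities of the three relation types and must sum to 1.
    ``model="er"`` switches to an Erdos-Renyi graph with the same expected
    edge count (tests use it when a closed-form oracle is easier there).
    """

    n_proteins: int = 2000
    attachment: int = 3
    type_mix: dict = field(
        default_factory=lambda: {
            "interactome": 0.5,
            "metabolome": 0.3,
            "signaling_other": 0.2,
        }
    )
    seed: int = 0
    model: str = "ba"

    def __post_init__(self) -> None:
        if self.n_proteins < 10:
            raise ValueError("n_proteins must be >= 10")
        if set(self.type_mix) - RELATION_TYPES:
            raise ValueError("type_mix keys must be relation types")
        probs = np.array(list(self.type_mix.values()), float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("type_mix must be nonnegative and sum to 1")
        if self.model not in ("ba", "er"):
            raise ValueError("model must be 'ba' or 'er'")


def generate_universe(spec: UniverseSpec) -> tuple[RelationStore, dict]:
    """Typed random universe plus a manifest of exact counts.

    The preferential-attachment graph is connected by construction; the
    Erdos-Renyi variant may not be (downstream analyses restrict to the
    largest component anyway).
    """
    if spec.model == "ba":
        g = nx.barabasi_albert_graph(spec.n_proteins, spec.attachment, seed=spec.seed)
    else:
        p = 2.0 * spec.attachment / (spec.n_proteins - 1)
        g = nx.fast_gnp_random_graph(spec.n_proteins, p, seed=spec.seed)
    rng = np.random.default_rng(spec.seed)
    type_names = sorted(spec.type_mix)
    probs = np.array([spec.type_mix[t] for t in type_names])
    edges = sorted((min(a, b), max(a, b)) for a, b in g.edges())
    draws = rng.choice(len(type_names), size=len(edges), p=probs)
    universe = CellMap(name=f"universe-{spec.model}-{spec.seed}")
    for nid in range(spec.n_proteins):
        universe.add_node(_protein_id(nid))
    for (a, b), t in zip(edges, draws):
        universe.add_edge(_protein_id(a), _protein_id(b), {type_names[t]}, provenance="synthetic")
    manifest = {
        "spec": {
            "n_proteins": spec.n_proteins,
            "attachment": spec.attachment,
            "type_mix": dict(spec.type_mix),
            "seed": spec.seed,
            "model": spec.model,
        },
        "n_nodes": universe.graph.number_of_nodes(),
        "n_edges": universe.graph.number_of_edges(),
        "type_counts": {
            type_names[k]: int((draws == k).sum()) for k in range(len(type_names))
        },
    }
    return RelationStore(universe), manifest


def sample_seed_proteins(store: RelationStore, n_seeds: int, seed: int = 0) -> list[str]:
    """Uniform, reproducible seed-protein draw from the universe."""
    rng = np.random.default_rng(seed)
    ids = sorted(store.protein_ids)
    if n_seeds > len(ids):
        raise ValueError("more seeds requested than proteins in the universe")
    pick = rng.choice(len(ids), size=n_seeds, replace=False)
    return sorted(ids[i] for i in pick)


@dataclass
class PlantedSpec:
    """A condition planted topologically close to a target seed set.

    Its effectors are drawn from the seeds' closed 1-jump neighbourhood
    (mostly neighbours rather than seeds themselves, so presence and
    distance signals stay distinguishable).
    """

    target_seeds: list[str]
    name: str = "planted"
    max_jumps: int = 1


@dataclass
class ConditionDbSpec:
    """Parameters of a synthetic condition database."""

    n_conditions: int = 160
    effectors_per_condition: tuple[int, int] = (20, 60)
    motives_per_condition: tuple[int, int] = (1, 3)
    planted: PlantedSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be >= 2")
        for lo, hi in (self.effectors_per_condition, self.motives_per_condition):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must be positive and ordered")


def _split_into_motives(effectors: list[str], n_motives: int, cond: str) -> list[Motive]:
    n_motives = min(n_motives, len(effectors))
    buckets: list[list[str]] = [[] for _ in range(n_motives)]
    for i, e in enumerate(effectors):
        buckets[i % n_motives].append(e)
    return [Motive(f"m{j + 1}", set(b)) for j, b in enumerate(buckets)]


def generate_condition_db(
    spec: ConditionDbSpec, store: RelationStore
) -> tuple[list[Condition], dict]:
    """Random conditions (uniform effector draws) plus an optional planted one.

    The planted condition samples its effectors from within
    ``planted.max_jumps`` of the target seed set; if that neighbourhood is
    smaller than the requested effector count an error naming the shortfall
    is raised.
    """
    rng = np.random.default_rng(spec.seed)
    ids = sorted(store.protein_ids)
    lo, hi = spec.effectors_per_condition
    mlo, mhi = spec.motives_per_condition
    if hi > len(ids):
        raise ValueError("effector range exceeds universe size")
    conditions: list[Condition] = []
    memberships: dict[str, list[str]] = {}
    for c in range(spec.n_conditions):
        name = f"C{c + 1:03d}"
        n_eff = int(rng.integers(lo, hi + 1))
        n_mot = int(rng.integers(mlo, mhi + 1))
        pick = rng.choice(len(ids), size=n_eff, replace=False)
        effectors = sorted(ids[i] for i in pick)
        conditions.append(Condition(name, _split_into_motives(effectors, n_mot, name)))
        memberships[name] = effectors

    if spec.planted is not None:
        p = spec.planted
        g = store.universe.graph
        neighbourhood: set[str] = set()
        frontier = {s for s in p.target_seeds if s in g}
        pool_seeds = set(frontier)
        for _ in range(p.max_jumps):
            nxt = set()
            for u in frontier:
                nxt.update(g.neighbors(u))
            neighbourhood |= nxt
            frontier = nxt
        neighbourhood -= pool_seeds  # prefer strict neighbours
        n_eff = int(rng.integers(lo, hi + 1))
        pool = sorted(neighbourhood) if len(neighbourhood) >= n_eff else sorted(
            neighbourhood | pool_seeds
        )
        if len(pool) < n_eff:
            raise ValueError(
                f"cannot plant condition: neighbourhood has {len(pool)} proteins, "
                f"{n_eff} needed"
            )
        pick = rng.choice(len(pool), size=n_eff, replace=False)
        effectors = sorted(pool[i] for i in pick)
        n_mot = int(rng.integers(mlo, mhi + 1))
        conditions.append(Condition(p.name, _split_into_motives(effectors, n_mot, p.name)))
        memberships[p.name] = effectors

    manifest = {
        "spec": {
            "n_conditions": spec.n_conditions,
            "effectors_per_condition": list(spec.effectors_per_condition),
            "motives_per_condition": list(spec.motives_per_condition),
            "seed": spec.seed,
            "planted": None if spec.planted is None else spec.planted.name,
        },
        "n_conditions": len(conditions),
        "n_memberships": sum(len(v) for v in memberships.values()),
        "memberships": memberships,
    }
    return conditions, manifest


# ----------------------------------------------------------------------
# fixture bundles

#: Scale presets: universe size/attachment, seed-set size, condition count.
#: paper_like targets a depth-1 map of roughly 3,000-4,000 proteins built
#: from 447 seeds, and a database of 161 conditions.
SCALES = {
    "small": dict(n_proteins=300, attachment=2, n_seeds=25, n_conditions=20,
                  effectors=(5, 15)),
    "paper_like": dict(n_proteins=16000, attachment=5, n_seeds=447, n_conditions=161,
                       effectors=(20, 60)),
}


def generate_fixture_bundle(outdir: str | Path, scale: str = "small", seed: int = 0) -> dict:
    """Write a complete, self-consistent input bundle to ``outdir``.

    Files: ``universe.sif``, ``seeds.txt``, ``conditions.gmt`` (the last
    condition is the planted one, named ``planted``) and ``manifest.json``
    with counts, the generating parameters and file checksums.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(SCALES)}")
    preset = SCALES[scale]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    store, uni_manifest = generate_universe(
        UniverseSpec(n_proteins=preset["n_proteins"], attachment=preset["attachment"], seed=seed)
    )
    seeds = sample_seed_proteins(store, preset["n_seeds"], seed=seed + 1)
    conditions, db_manifest = generate_condition_db(
        ConditionDbSpec(
            n_conditions=preset["n_conditions"] - 1,  # + 1 planted = preset total
            effectors_per_condition=preset["effectors"],
            planted=PlantedSpec(target_seeds=seeds),
            seed=seed + 2,
        ),
        store,
    )

    from . import io

    universe_path = outdir / "universe.sif"
    seeds_path = outdir / "seeds.txt"
    conditions_path = outdir / "conditions.gmt"
    io.write_sif(store.universe, universe_path)
    io.write_seed_list(seeds, seeds_path)
    write_condition_db(conditions, conditions_path, fmt="gmt")

    def sha(p: Path) -> str:
        return hashlib.sha256(p.read_bytes()).hexdigest()

    manifest = {
        "scale": scale,
        "seed": seed,
        "universe": uni_manifest,
        "n_seeds": len(seeds),
        "conditions": {k: v for k, v in db_manifest.items() if k != "memberships"},
        "n_effector_memberships": db_manifest["n_memberships"],
        "files": {
            "universe.sif": sha(universe_path),
            "seeds.txt": sha(seeds_path),
            "conditions.gmt": sha(conditions_path),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["memberships"] = db_manifest["memberships"]
    return manifest
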