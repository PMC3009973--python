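"""Condition-map construction by recursive expansion from seed proteins.

A :class:`RelationStore` holds the relationship universe (the role played by
public interaction/pathway snapshots).  :func:`build_map` grows a map outward
from a seed set: every protein within ``depth`` jumps of any seed is
included, together with *all* universe edges among included proteins
(induced closure), so local wiring is preserved, not just a search tree.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .graph import CellMap, map_summary

logger = logging.getLogger(__name__)


class RelationStore:
    """Adjacency-indexed universe of typed protein relationships.

    Backed by a :class:`CellMap` so the same ingest rules apply (self-loops
    dropped, parallel records merged with type union); lookups from either
    endpoint return the same edge.
    """

    def __init__(self, universe: CellMap) -> None:
        self.universe = universe

    @classmethod
    def from_file(cls, path: str | Path) -> "RelationStore":
        from . import io

        p = str(path)
        if p.endswith(".graphml"):
            return cls(io.read_graphml(p))
        return cls(io.read_sif(p))

    @property
    def protein_ids(self) -> set[str]:
        return self.universe.node_ids

    def neighbors(self, protein_id: str) -> set[str]:
        return set(self.universe.graph.neighbors(protein_id))

    def edges_of(self, protein_id: str):
        g = self.universe.graph
        for _, b, d in g.edges(protein_id, data=True):
            yield protein_id, b, d["types"], d.get("provenance", "")

    def __len__(self) -> int:
        return self.universe.graph.number_of_edges()


def build_map(
    seeds: Iterable[str], store: RelationStore, depth: int = 1, name: str = "map"
) -> CellMap:
    """Induced subgraph on all proteins within ``depth`` jumps of any seed.

    Seeds absent from the universe are kept as isolated nodes (with a
    logged warning) so presence statistics against the seed list remain
    well-defined.  Seed nodes carry ``is_seed=True``.  Deterministic for
    fixed inputs.
    """
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValueError("empty seeds")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    g = store.universe.graph
    in_universe = [s for s in seeds if s in g]
    missing = [s for s in seeds if s not in g]
    if missing:
        logger.warning(
            "%d seed(s) absent from universe, kept isolated (e.g. %r)",
            len(missing),
            missing[0],
        )
    frontier = set(in_universe)
    reached = set(in_universe)
    for _ in range(depth):
        if not frontier:
            break
        nxt = set()
        for u in frontier:
            nxt.update(g.neighbors(u))
        frontier = nxt - reached
        reached |= frontier

    cell_map = store.universe.subgraph(reached, name=name)
    for s in seeds:
        cell_map.add_node(s, is_seed=True)  # also materialises missing seeds
    return cell_map


def expansion_profile(
    seeds: Iterable[str], store: RelationStore, max_depth: int
) -> pd.DataFrame:
    """Growth table ``(depth, n_nodes, n_edges)`` for depths 0..max_depth.

    Row at depth d matches ``map_summary(build_map(seeds, store, d))``;
    both counts are nondecreasing in d.  Useful for choosing an expansion
    depth that yields a map of the desired size.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    seeds = sorted(set(seeds))
    rows = []
    for d in range(max_depth + 1):
        s = map_summary(build_map(seeds, store, d))
        rows.append({"depth": d, "n_nodes": s.n_nodes, "n_edges": s.n_edges})
    return pd.DataFrame(rows)


@dataclass
class BuildMetadata:
    """Sidecar record describing a map build (written as JSON by the CLI)."""

    n_seeds: int
    depth: int
    universe_sha256: str
    n_nodes: int
    n_edges: int

    @staticmethod
    def checksum(path: str | Path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        return h.hexdigest()
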