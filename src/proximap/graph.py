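"""Graph data model and shortest-path ("jump") machinery.

A condition map (:class:`CellMap`) is an undirected graph whose nodes are
protein accessions and whose edges are typed molecular relationships
(physical interaction, metabolic coupling, signaling/other).  All distances
in this package are *jumps*: minimum numbers of edges traversed.  Edge types
never weight a jump; directionality metadata, where present in the source
records, is preserved as provenance but ignored for distance purposes, since
the set-to-set statistics downstream are symmetric by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

#: The three relationship classes a typed edge may carry.
RELATION_TYPES = frozenset({"interactome", "metabolome", "signaling_other"})


@dataclass
class ProteinNode:
    """A protein in a map: accession id, optional synonyms, seed flag, tags."""

    id: str
    labels: list[str] = field(default_factory=list)
    is_seed: bool = False
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be a nonempty string")


@dataclass(frozen=True)
class RelationEdge:
    """An undirected typed relationship between two distinct proteins.

    ``types`` is a nonempty frozenset drawn from :data:`RELATION_TYPES`;
    parallel records between the same pair are merged upstream by taking
    the union of their type sets.
    """

    a: str
    b: str
    types: frozenset = frozenset({"interactome"})
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-loop on {self.a!r} is not a valid edge")
        if not self.types:
            raise ValueError("edge must carry at least one relation type")
        unknown = set(self.types) - RELATION_TYPES
        if unknown:
            raise ValueError(f"unknown relation types: {sorted(unknown)}")

    @property
    def key(self) -> tuple[str, str]:
        """Canonical unordered endpoint pair."""
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclass
class MapSummary:
    n_nodes: int
    n_edges: int
    n_seeds: int
    degree_quartiles: tuple[float, float, float]
    n_components: int


class CellMap:
    """A named, typed, undirected protein-relationship graph.

    Thin wrapper over :class:`networkx.Graph` that enforces the map
    invariants at ingest: node ids unique and nonempty, self-loops dropped
    with a warning, parallel edge records merged with type-set union, and
    every edge endpoint materialised as a node.
    """

    def __init__(self, name: str = "map") -> None:
        self.name = name
        self._g = nx.Graph()

    # -- construction -------------------------------------------------

    def add_node(
        self,
        node_id: str,
        *,
        labels: Iterable[str] = (),
        is_seed: bool = False,
        **annotations,
    ) -> None:
        if not node_id:
            raise ValueError("protein id must be a nonempty string")
        if node_id in self._g:
            # merging: seed flag is sticky, labels accumulate
            data = self._g.nodes[node_id]
            data["is_seed"] = data["is_seed"] or is_seed
            data["labels"] = sorted(set(data["labels"]) | set(labels))
            data["annotations"].update(annotations)
        else:
            self._g.add_node(
                node_id,
                labels=sorted(set(labels)),
                is_seed=bool(is_seed),
                annotations=dict(annotations),
            )

    def add_edge(
        self,
        a: str,
        b: str,
        types: Iterable[str] = ("interactome",),
        provenance: str = "",
    ) -> None:
        if a == b:
            logger.warning("dropping self-loop on %r", a)
            self.add_node(a)
            return
        types = frozenset(types)
        RelationEdge(a, b, types, provenance)  # validate
        self.add_node(a)
        self.add_node(b)
        if self._g.has_edge(a, b):
            data = self._g.edges[a, b]
            data["types"] = data["types"] | types
            if provenance and provenance not in data["provenance"]:
                data["provenance"] = ";".join(
                    p for p in (data["provenance"], provenance) if p
                )
        else:
            self._g.add_edge(a, b, types=types, provenance=provenance)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple] | Iterable[RelationEdge],
        name: str = "map",
        seeds: Iterable[str] = (),
    ) -> "CellMap":
        """Build a map from ``(a, b)`` / ``(a, b, types)`` tuples or edges."""
        m = cls(name)
        for e in edges:
            if isinstance(e, RelationEdge):
                m.add_edge(e.a, e.b, e.types, e.provenance)
            else:
                m.add_edge(*e)
        for s in seeds:
            m.add_node(s, is_seed=True)
        return m

    # -- views ---------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying undirected networkx graph (shared, not a copy)."""
        return self._g

    @property
    def node_ids(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def seed_ids(self) -> set[str]:
        return {n for n, d in self._g.nodes(data=True) if d.get("is_seed")}

    def nodes(self) -> Iterator[ProteinNode]:
        for n, d in self._g.nodes(data=True):
            yield ProteinNode(n, list(d["labels"]), d["is_seed"], dict(d["annotations"]))

    def edges(self) -> Iterator[RelationEdge]:
        for a, b, d in self._g.edges(data=True):
            x, y = (a, b) if a <= b else (b, a)
            yield RelationEdge(x, y, d["types"], d.get("provenance", ""))

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def subgraph(self, node_ids: Iterable[str], name: str | None = None) -> "CellMap":
        """Induced subgraph on ``node_ids`` as a new independent map."""
        sub = CellMap(name or self.name)
        sub._g = self._g.subgraph(node_ids).copy()
        return sub


# ----------------------------------------------------------------------
# operations


def bfs_jumps(cell_map: CellMap, sources: Iterable[str]) -> dict[str, int]:
    """Minimum jump count from any source to every reachable node.

    Sources map to 0; nodes unreachable from every source are absent from
    the returned mapping.  Raises on an empty source set or a source id not
    present in the map.
    """
    sources = set(sources)
    if not sources:
        raise ValueError("empty node set")
    missing = sources - cell_map.node_ids
    if missing:
        raise KeyError(f"source not in map: {sorted(missing)[0]!r}")
    g = cell_map.graph
    from collections import deque

    dist = {s: 0 for s in sources}
    queue = deque(sorted(sources))
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def largest_component(cell_map: CellMap) -> CellMap:
    """Induced subgraph on the largest connected component.

    Ties between equal-size components are broken in favour of the
    component containing the lexicographically smallest node id.
    """
    if len(cell_map) == 0:
        raise ValueError("empty map")
    comps = sorted(nx.connected_components(cell_map.graph), key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    dropped = len(cell_map) - len(keep)
    if dropped:
        logger.info("largest_component: dropped %d of %d nodes", dropped, len(cell_map))
    return cell_map.subgraph(keep)


def map_summary(cell_map: CellMap) -> MapSummary:
    """Exact node/edge/seed counts, degree quartiles and component count.

    Degree counts each neighbour once regardless of how many relation types
    the connecting edge carries.
    """
    g = cell_map.graph
    n = g.number_of_nodes()
    if n == 0:
        return MapSummary(0, 0, 0, (0.0, 0.0, 0.0), 0)
    import numpy as np

    degrees = np.fromiter((d for _, d in g.degree()), dtype=float, count=n)
    q1, q2, q3 = (float(q) for q in np.percentile(degrees, [25, 50, 75]))
    return MapSummary(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        n_seeds=len(cell_map.seed_ids),
        degree_quartiles=(q1, q2, q3),
        n_components=nx.number_connected_components(g),
    )
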