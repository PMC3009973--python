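"""Readers and writers for maps, universes and seed lists.

Three interchange formats are supported for relationship graphs:

* SIF: ``node <TAB> relation <TAB> node`` (one partner per line);
* a 3-column TSV dialect ``a <TAB> type <TAB> b`` with a ``#`` comment
  convention (identical grammar to SIF; kept as a named dialect because
  exports in the wild put the relation in either column order);
* GraphML, via networkx, for lossless round-trips including seed flags.

Edges whose relation field contains ``+``-joined types (e.g.
``interactome+metabolome``) round-trip as multi-type edges.  Seed lists are
plain text, one accession per line, ``#`` starting a comment.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx

from .graph import CellMap

logger = logging.getLogger(__name__)

_TYPE_SEP = "+"


def _parse_relation_lines(lines: Iterable[str], path: str) -> CellMap:
    m = CellMap(name=Path(path).stem)
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:  # lone node declaration, SIF allows it
            m.add_node(parts[0].strip())
            continue
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 'a<TAB>type<TAB>b', got {line!r}")
        a, rel, *partners = (p.strip() for p in parts)
        types = frozenset(rel.split(_TYPE_SEP))
        for b in partners:
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
                m.add_node(a)
            else:
                m.add_edge(a, b, types)
    return m


def read_sif(path: str | Path) -> CellMap:
    """Read a SIF / 3-column-TSV relationship file into a :class:`CellMap`."""
    with open(path) as fh:
        return _parse_relation_lines(fh, str(path))


# the TSV dialect shares the SIF grammar (a, type, b)
read_relations_tsv = read_sif


def write_sif(cell_map: CellMap, path: str | Path) -> None:
    """Write edges as ``a<TAB>types<TAB>b`` with sorted, canonical order."""
    with open(path, "w") as fh:
        for e in sorted(cell_map.edges(), key=lambda e: e.key):
            fh.write(f"{e.a}\t{_TYPE_SEP.join(sorted(e.types))}\t{e.b}\n")
        for nid in sorted(cell_map.node_ids):
            if cell_map.graph.degree(nid) == 0:
                fh.write(f"{nid}\n")


write_relations_tsv = write_sif


def read_graphml(path: str | Path) -> CellMap:
    g = nx.read_graphml(path)
    m = CellMap(name=Path(str(path)).stem)
    for n, d in g.nodes(data=True):
        labels = [s for s in d.get("labels", "").split("|") if s]
        m.add_node(str(n), labels=labels, is_seed=bool(d.get("is_seed", False)))
    for a, b, d in g.edges(data=True):
        types = frozenset(t for t in d.get("types", "interactome").split(_TYPE_SEP) if t)
        m.add_edge(str(a), str(b), types, d.get("provenance", ""))
    return m


def write_graphml(cell_map: CellMap, path: str | Path) -> None:
    g = nx.Graph()
    for node in cell_map.nodes():
        g.add_node(node.id, labels="|".join(node.labels), is_seed=node.is_seed)
    for e in cell_map.edges():
        g.add_edge(e.a, e.b, types=_TYPE_SEP.join(sorted(e.types)), provenance=e.provenance)
    nx.write_graphml(g, path)


def read_seed_list(path: str | Path) -> list[str]:
    """One accession per line; ``#`` comments and blank lines ignored."""
    seeds: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line and line not in seen:
                seeds.append(line)
                seen.add(line)
    return seeds


def write_seed_list(seeds: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seeds:
            fh.write(f"{s}\n")
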