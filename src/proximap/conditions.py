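"""Condition database model and presence analysis.

A *condition* (disease, syndrome or physiological state) is described by
one or more pathophysiological *motives* (sub-mechanisms, e.g. insulin
resistance), each carrying the set of *effector proteins* held responsible
for the phenotype.  A condition's effector set is the exact union of its
motive sets.

Presence analysis reports how many of a condition's effectors are contained
in a map.  Percentages use the FLOOR convention: pct = floor(100·k/n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .graph import CellMap

logger = logging.getLogger(__name__)


@dataclass
class Motive:
    """A named pathophysiological sub-mechanism with its effector set."""

    name: str
    effectors: set[str]

    def __post_init__(self) -> None:
        if not self.effectors:
            raise ValueError(f"motive {self.name!r} has no effectors")
        if any(not e for e in self.effectors):
            raise ValueError(f"motive {self.name!r} has an empty effector id")


@dataclass
class Condition:
    """A characterised condition: named motives plus their pooled effectors."""

    name: str
    motives: list[Motive] = field(default_factory=list)

    @property
    def effectors(self) -> set[str]:
        out: set[str] = set()
        for m in self.motives:
            out |= m.effectors
        return out


@dataclass
class PresenceResult:
    n_total: int
    n_present: int
    pct: int  # floor(100 * n_present / n_total)
    present_ids: set[str]


def presence(effectors: Iterable[str], cell_map: CellMap) -> PresenceResult:
    """Fraction of an effector set contained in the map (floor percent)."""
    effectors = set(effectors)
    if not effectors:
        raise ValueError("empty node set")
    present = effectors & cell_map.node_ids
    n_total, n_present = len(effectors), len(present)
    return PresenceResult(n_total, n_present, (100 * n_present) // n_total, present)


# ----------------------------------------------------------------------
# database I/O — GMT dialect and long TSV


def _assemble(records: list[tuple[str, str, str]], path: str) -> list[Condition]:
    """(condition, motive, protein) records -> Condition list, input order."""
    order: list[str] = []
    motives: dict[str, dict[str, list[str]]] = {}
    for cond, mot, prot in records:
        if cond not in motives:
            motives[cond] = {}
            order.append(cond)
        bucket = motives[cond].setdefault(mot, [])
        if prot in bucket:
            logger.warning("%s: duplicate effector %r in %s|%s, ignored", path, prot, cond, mot)
        else:
            bucket.append(prot)
    return [
        Condition(c, [Motive(m, set(ps)) for m, ps in motives[c].items()]) for c in order
    ]


def load_condition_db(path: str | Path) -> list[Condition]:
    """Load a condition database from GMT or long-TSV.

    GMT dialect: ``condition|motive <TAB> description <TAB> id ...`` — one
    motive per line, motives grouped under their condition.  Long TSV:
    three columns ``condition <TAB> motive <TAB> protein`` (an optional
    header row with exactly these names is skipped).  Both encodings of the
    same database yield identical Condition lists.
    """
    path = str(path)
    records: list[tuple[str, str, str]] = []
    n_data_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            n_data_lines += 1
            if "|" in parts[0]:  # GMT dialect: set-name, description, members...
                cond, mot = parts[0].split("|", 1)
                members = [p.strip() for p in parts[2:] if p.strip()]
                if not members:
                    raise ValueError(f"{path}:{lineno}: motive {parts[0]!r} has no members")
                for prot in members:
                    records.append((cond.strip(), mot.strip(), prot))
            else:  # long TSV
                cond, mot, prot = (p.strip() for p in parts[:3])
                if n_data_lines == 1 and (cond, mot, prot) == ("condition", "motive", "protein"):
                    continue
                if not (cond and mot and prot):
                    raise ValueError(f"{path}:{lineno}: empty field")
                records.append((cond, mot, prot))
    if not records:
        raise ValueError(f"{path}: empty condition database")
    conditions = _assemble(records, path)
    names = [c.name for c in conditions]
    if len(names) != len(set(names)):
        raise ValueError(f"{path}: duplicate condition names")
    return conditions


def write_condition_db(
    conditions: Iterable[Condition], path: str | Path, fmt: str = "gmt"
) -> None:
    """Write a database as GMT (default) or long TSV, in deterministic order."""
    with open(path, "w") as fh:
        if fmt == "gmt":
            for c in conditions:
                for m in c.motives:
                    ids = "\t".join(sorted(m.effectors))
                    fh.write(f"{c.name}|{m.name}\t-\t{ids}\n")
        elif fmt == "tsv":
            fh.write("condition\tmotive\tprotein\n")
            for c in conditions:
                for m in c.motives:
                    for p in sorted(m.effectors):
                        fh.write(f"{c.name}\t{m.name}\t{p}\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")
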