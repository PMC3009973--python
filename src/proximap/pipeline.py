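"""End-to-end analysis: build -> presence -> distance/null -> embed -> density -> links.

``run_analysis`` drives the whole workflow from a single
:class:`AnalysisConfig` (usually loaded from YAML).  Every stage writes its
artifact to the output directory and downstream stages re-read those files
from disk, so any single stage can be rerun in isolation with identical
results and no hidden in-memory state.  A run manifest records all
settings in force, file checksums, and completion status.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

_GRID_FMT = "%.17g"


@dataclass
class AnalysisConfig:
    """Everything a full run needs; exactly mirrors the YAML schema."""

    universe: str = "universe.sif"
    seeds: str = "seeds.txt"
    conditions: str = "conditions.gmt"
    focal_condition: str = "planted"
    depth: int = 1
    statistic: str = "pooled_mean"  # pooled_mean | mean_of_means | min_pairwise
    k_jumps: int = 2
    embedding_method: str = "classical"  # classical | smacof
    embedding_seed: int = 0
    density_resolution: int = 256
    density_mode: str = "kde"  # kde | count
    density_bandwidth: float | None = None  # None -> Scott's rule
    outdir: str = "proximap-run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    def validate(self) -> None:
        for attr in ("universe", "seeds", "conditions"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.k_jumps < 1:
            raise ValueError("k_jumps must be >= 1")


def default_config_yaml() -> str:
    """The fully-commented default config emitted by ``init-config``."""
    cfg = AnalysisConfig()
    header = (
        "# proximap analysis configuration\n"
        "# Every under-determined analysis choice is surfaced here so runs\n"
        "# are self-documenting: expansion depth, distance statistic\n"
        "# (pooled_mean averages all directed minima in one pool;\n"
        "# mean_of_means weights both sets equally), the k-jump radius for\n"
        "# protein-level links, the MDS variant, and the density grid.\n"
    )
    return header + cfg.to_yaml()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_grid(grid, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mode={grid.mode} bandwidth={grid.bandwidth!r} n_points={grid.n_points}\n")
        fh.write(
            "# extent="
            + ",".join(repr(float(v)) for v in grid.extent)
            + f" resolution={grid.resolution[0]}x{grid.resolution[1]}\n"
        )
        np.savetxt(fh, grid.values, fmt=_GRID_FMT, delimiter="\t")


def run_analysis(config: AnalysisConfig, quiet: bool = False) -> dict:
    """Run the full pipeline; returns the manifest dict (also written).

    Any stage failure aborts with the stage name attached; the manifest on
    disk then marks the run incomplete.
    """
    from . import io
    from .builder import BuildMetadata, RelationStore, build_map
    from .conditions import load_condition_db, presence
    from .density import cluster_overlay, peak_regions
    from .embedding import geodesic_mds
    from .graph import map_summary
    from .links import k_jump_links, motive_breakdown
    from .proximity import null_distribution, percentile_of, set_distance

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stages": {},
        "complete": False,
        "artifacts": {},
    }
    manifest_path = outdir / "manifest.json"

    def _checkpoint() -> None:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                if not quiet:
                    logger.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    manifest["stages"][name] = "failed"
                    _checkpoint()
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"][name] = "ok"
                if not quiet:
                    logger.info("stage %s done (%.2fs)", name, time.perf_counter() - self_inner.t0)
                return False

        return _Ctx()

    map_path = outdir / "map.graphml"
    with _stage("build"):
        store = RelationStore.from_file(config.universe)
        seeds = io.read_seed_list(config.seeds)
        cell_map = build_map(seeds, store, config.depth, name="condition-map")
        io.write_graphml(cell_map, map_path)
        summary = map_summary(cell_map)
        meta = BuildMetadata(
            n_seeds=len(seeds),
            depth=config.depth,
            universe_sha256=BuildMetadata.checksum(config.universe),
            n_nodes=summary.n_nodes,
            n_edges=summary.n_edges,
        )
        (outdir / "build_meta.json").write_text(json.dumps(asdict(meta), indent=2))
        manifest["map"] = {"n_nodes": summary.n_nodes, "n_edges": summary.n_edges,
                           "n_seeds": summary.n_seeds}

    with _stage("presence"):
        cell_map = io.read_graphml(map_path)  # re-read: no hidden state
        conditions = load_condition_db(config.conditions)
        rows = ["condition\tmotive\tn_total\tn_present\tpct"]
        for c in conditions:
            r = presence(c.effectors, cell_map)
            rows.append(f"{c.name}\t-\t{r.n_total}\t{r.n_present}\t{r.pct}")
            for m in c.motives:
                rm = presence(m.effectors, cell_map)
                rows.append(f"{c.name}\t{m.name}\t{rm.n_total}\t{rm.n_present}\t{rm.pct}")
        (outdir / "presence.tsv").write_text("\n".join(rows) + "\n")

    with _stage("distance"):
        cell_map = io.read_graphml(map_path)
        conditions = load_condition_db(config.conditions)
        focal = next((c for c in conditions if c.name == config.focal_condition), None)
        if focal is None:
            raise ValueError(f"focal condition {config.focal_condition!r} not in database")
        seeds = io.read_seed_list(config.seeds)
        null = null_distribution(cell_map, conditions, config.statistic)
        with open(outdir / "null.tsv", "w") as fh:
            fh.write(f"# statistic={config.statistic} n_comparisons={null.n_comparisons}\n")
            fh.write(f"# mean={null.mean!r} sd={null.sd!r}\n")
            null.to_frame().to_csv(fh, sep="\t", index=False)
        focal_sd = set_distance(cell_map, set(seeds), focal.effectors)
        d = focal_sd[config.statistic]
        report = {
            "focal_condition": focal.name,
            "statistic": config.statistic,
            "distance": d,
            "set_distance": asdict(focal_sd),
            "percentile_empirical": percentile_of(null, d),
            "percentile_normal_fit": percentile_of(null, d, kind="normal"),
            "null": {"n_comparisons": null.n_comparisons, "mean": null.mean, "sd": null.sd},
        }
        (outdir / "distance.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    coords_path = outdir / "coords.tsv"
    with _stage("embed"):
        cell_map = io.read_graphml(map_path)
        emb = geodesic_mds(cell_map, seed=config.embedding_seed, method=config.embedding_method)
        with open(coords_path, "w") as fh:
            fh.write(f"# method={emb.method} stress={emb.stress!r} "
                     f"n_excluded={len(emb.component_note)}\n")
            fh.write("id\tx\ty\n")
            for nid in sorted(emb.coords):
                x, y = emb.coords[nid]
                fh.write(f"{nid}\t{x!r}\t{y!r}\n")

    with _stage("density"):
        from .embedding import Embedding2D

        coords = {}
        with open(coords_path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("id\t"):
                    continue
                nid, x, y = line.rstrip("\n").split("\t")
                coords[nid] = (float(x), float(y))
        emb = Embedding2D(coords=coords, stress=float("nan"))
        conditions = load_condition_db(config.conditions)
        focal = next(c for c in conditions if c.name == config.focal_condition)
        res = (config.density_resolution, config.density_resolution)
        overlays = {"condition": focal.effectors}
        for m in focal.motives:
            overlays[f"motive_{m.name}"] = m.effectors
        peak_report = {}
        background = None
        for tag, ids in overlays.items():
            eff = set(ids) & set(coords)
            if not eff:
                logger.warning("density: %s has no embedded proteins, skipped", tag)
                continue
            bg, ov = cluster_overlay(
                emb, set(coords), eff, res, config.density_mode, config.density_bandwidth
            )
            if background is None:
                background = bg
                _write_grid(bg, outdir / "density_background.tsv")
            _write_grid(ov, outdir / f"density_{tag}.tsv")
            regions = peak_regions(ov, 0.9)
            peak_report[tag] = [
                {"mass": r.mass, "n_cells": len(r.cells), "top_left": list(r.top_left)}
                for r in regions[:5]
            ]
        (outdir / "density_peaks.json").write_text(
            json.dumps(peak_report, indent=2, sort_keys=True)
        )

    with _stage("links"):
        cell_map = io.read_graphml(map_path)
        conditions = load_condition_db(config.conditions)
        focal = next(c for c in conditions if c.name == config.focal_condition)
        seeds = set(io.read_seed_list(config.seeds))
        report = k_jump_links(cell_map, seeds, focal.effectors, config.k_jumps)
        with open(outdir / "links.tsv", "w") as fh:
            fh.write(f"# k={config.k_jumps} n_direct={report.n_direct} "
                     f"n_relationships={report.n_relationships} "
                     f"n_effectors_involved={report.n_effectors_involved} "
                     f"n_seeds_involved={report.n_seeds_involved}\n")
            report.to_frame().to_csv(fh, sep="\t", index=False)
        motive_breakdown(report, focal.motives).to_csv(
            outdir / "links_by_motive.tsv", sep="\t", index=False
        )
        manifest["links"] = {
            "n_direct": report.n_direct,
            "n_relationships": report.n_relationships,
        }

    for artifact in sorted(outdir.iterdir()):
        if artifact.name != "manifest.json":
            manifest["artifacts"][artifact.name] = _sha256(artifact)
    manifest["complete"] = True
    _checkpoint()
    return manifest
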