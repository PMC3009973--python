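"""Shared fixtures: tiny hand-built maps and seeded synthetic bundles."""

from __future__ import annotations

import pytest

from proximap import CellMap, UniverseSpec, generate_fixture_bundle, generate_universe


def make_path_map(n: int = 5, prefix: str = "v") -> CellMap:
    """Path graph v1-v2-...-vn (zero-padded so ids sort in path order)."""
    width = len(str(n))
    ids = [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]
    return CellMap.from_edges([(a, b) for a, b in zip(ids, ids[1:])], name=f"P{n}")


@pytest.fixture
def path5() -> CellMap:
    return make_path_map(5)


@pytest.fixture
def triangle() -> CellMap:
    return CellMap.from_edges([("a", "b"), ("b", "c"), ("a", "c")], name="triangle")


@pytest.fixture(scope="session")
def small_store():
    """Seeded 300-protein preferential-attachment universe."""
    store, manifest = generate_universe(UniverseSpec(n_proteins=300, attachment=2, seed=7))
    return store, manifest


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small on-disk fixture bundle (universe + seeds + conditions)."""
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = generate_fixture_bundle(outdir, scale="small", seed=11)
    return outdir, manifest
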