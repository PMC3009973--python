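"""Set-to-set distances, the all-pairs null and percentile significance."""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from proximap import (
    CellMap,
    Condition,
    Motive,
    NullDistribution,
    anchored_null,
    largest_component,
    null_distribution,
    pathway_to_motive_distances,
    percentile_of,
    set_distance,
)


def brute_force_set_distance(cell_map: CellMap, a: set, b: set):
    """Independent oracle: all-pairs Floyd-Warshall over the largest
    component, directed minima by explicit double loops."""
    comp = largest_component(cell_map)
    dist = {u: dict(v) for u, v in nx.floyd_warshall(comp.graph).items()}
    a_in, b_in = a & comp.node_ids, b & comp.node_ids
    fwd = [min(dist[x][y] for y in b_in) for x in sorted(a_in)]
    rev = [min(dist[y][x] for x in a_in) for y in sorted(b_in)]
    return {
        "pooled_mean": math.fsum(fwd + rev) / (len(fwd) + len(rev)),
        "mean_of_means": (math.fsum(fwd) / len(fwd) + math.fsum(rev) / len(rev)) / 2,
        "min_pairwise": int(min(fwd + rev)),
        "hausdorff_max": int(max(fwd + rev)),
    }


class TestSetDistance:
    def test_set_to_itself_is_zero_everywhere(self, path5):
        sd = set_distance(path5, {"v1", "v3"}, {"v1", "v3"})
        assert (
            sd.forward_mean, sd.reverse_mean, sd.pooled_mean,
            sd.mean_of_means, sd.min_pairwise, sd.hausdorff_max,
        ) == (0.0, 0.0, 0.0, 0.0, 0, 0)

    def test_adjacent_singletons(self):
        m = CellMap.from_edges([("u", "v")])
        sd = set_distance(m, {"u"}, {"v"})
        assert sd.pooled_mean == sd.mean_of_means == 1.0
        assert sd.min_pairwise == 1

    def test_path_example_directed_minima(self, path5):
        """A={v1}, B={v4,v5}: minima are v1->B:3, v4->A:3, v5->A:4."""
        sd = set_distance(path5, {"v1"}, {"v4", "v5"})
        assert sd.forward_mean == 3.0
        assert sd.reverse_mean == 3.5
        assert sd.pooled_mean == pytest.approx(10.0 / 3.0)
        assert sd.mean_of_means == 3.25
        assert sd.min_pairwise == 3
        oracle = brute_force_set_distance(path5, {"v1"}, {"v4", "v5"})
        for k, v in oracle.items():
            assert getattr(sd, k) == pytest.approx(v)

    def test_out_of_component_proteins_dropped_and_counted(self):
        m = CellMap.from_edges([("a", "b"), ("b", "c"), ("x", "y")])
        sd = set_distance(m, {"a", "x"}, {"c", "GHOST_NOT_IN_MAP"})
        assert sd.n_dropped == 2
        assert (sd.n_a, sd.n_b) == (1, 1)
        assert sd.pooled_mean == 2.0

    def test_no_representative_raises(self):
        m = CellMap.from_edges([("a", "b"), ("b", "c"), ("x", "y")])
        with pytest.raises(ValueError, match="no representatives"):
            set_distance(m, {"a"}, {"x"})  # x outside the largest component
        with pytest.raises(ValueError, match="empty node set"):
            set_distance(m, set(), {"a"})

    def test_symmetry_and_bounds(self, small_store):
        """pooled_mean/mean_of_means/min_pairwise are symmetric in (A, B);
        pooled and mean-of-means lie between the directed means; pooled
        >= min_pairwise."""
        store, _ = small_store
        m = store.universe
        ids = sorted(m.node_ids)
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = set(rng.choice(ids, 8, replace=False))
            b = set(rng.choice(ids, 5, replace=False))
            ab, ba = set_distance(m, a, b), set_distance(m, b, a)
            assert ab.pooled_mean == ba.pooled_mean
            assert ab.mean_of_means == ba.mean_of_means
            assert ab.min_pairwise == ba.min_pairwise
            lo = min(ab.forward_mean, ab.reverse_mean)
            hi = max(ab.forward_mean, ab.reverse_mean)
            assert lo - 1e-12 <= ab.pooled_mean <= hi + 1e-12
            assert lo - 1e-12 <= ab.mean_of_means <= hi + 1e-12
            assert ab.pooled_mean >= ab.min_pairwise

    def test_matches_brute_force_on_random_graphs(self):
        """Exhaustive-oracle agreement on seeded random graphs."""
        rng = np.random.default_rng(17)
        for trial in range(10):
            g = nx.gnp_random_graph(25, 0.12, seed=100 + trial)
            m = CellMap.from_edges([(f"n{a:02d}", f"n{b:02d}") for a, b in g.edges()])
            comp = largest_component(m)
            ids = sorted(comp.node_ids)
            if len(ids) < 6:
                continue
            a = set(rng.choice(ids, 4, replace=False))
            b = set(rng.choice(ids, 3, replace=False))
            sd = set_distance(m, a, b)
            oracle = brute_force_set_distance(m, a, b)
            assert sd.pooled_mean == pytest.approx(oracle["pooled_mean"], abs=1e-12)
            assert sd.mean_of_means == pytest.approx(oracle["mean_of_means"], abs=1e-12)
            assert sd.min_pairwise == oracle["min_pairwise"]
            assert sd.hausdorff_max == oracle["hausdorff_max"]


def _conditions_from_sets(named_sets):
    return [Condition(n, [Motive("m1", set(s))]) for n, s in named_sets]


class TestNullDistribution:
    def test_three_conditions_three_comparisons(self, path5):
        db = _conditions_from_sets(
            [("c1", {"v1"}), ("c2", {"v3"}), ("c3", {"v5"})]
        )
        null = null_distribution(path5, db)
        assert null.n_comparisons == 3
        assert sorted(null.values) == [2.0, 2.0, 4.0]

    def test_identical_conditions_degenerate_null(self, path5):
        db = _conditions_from_sets(
            [("c1", {"v1", "v2"}), ("c2", {"v1", "v2"}), ("c3", {"v1", "v2"})]
        )
        null = null_distribution(path5, db)
        assert set(null.values) == {0.0}
        assert null.sd == 0.0

    def test_unrepresented_condition_skipped_with_warning(self, path5, caplog):
        db = _conditions_from_sets(
            [("c1", {"v1"}), ("c2", {"v4"}), ("ghostly", {"zzz"})]
        )
        with caplog.at_level("WARNING"):
            null = null_distribution(path5, db)
        assert null.n_comparisons == 1
        assert null.skipped == ["ghostly"]
        assert "ghostly" in caplog.text

    def test_fewer_than_two_usable_conditions_raises(self, path5):
        db = _conditions_from_sets([("c1", {"v1"}), ("ghost", {"zzz"})])
        with pytest.raises(ValueError, match=">= 2 conditions"):
            null_distribution(path5, db)

    def test_matches_naive_double_loop(self, small_store):
        """Mean/sd of the fast all-pairs sweep equal a naive recomputation
        with per-pair set_distance calls."""
        store, _ = small_store
        m = store.universe
        ids = sorted(m.node_ids)
        rng = np.random.default_rng(23)
        db = _conditions_from_sets(
            [(f"c{i:02d}", set(rng.choice(ids, 6, replace=False))) for i in range(12)]
        )
        null = null_distribution(m, db, "pooled_mean")
        assert null.n_comparisons == 12 * 11 // 2
        naive = [
            set_distance(m, a.effectors, b.effectors).pooled_mean
            for a, b in combinations(db, 2)
        ]
        assert null.values == pytest.approx(naive, abs=1e-12)
        assert null.mean == pytest.approx(float(np.mean(naive)), abs=1e-12)
        assert null.sd == pytest.approx(float(np.std(naive, ddof=1)), abs=1e-12)


class TestAnchoredNull:
    def test_one_value_per_condition_equal_to_set_distance(self, small_store):
        """Anchor-vs-all-conditions distances match per-condition
        set_distance calls, in condition order."""
        store, _ = small_store
        m = store.universe
        ids = sorted(m.node_ids)
        rng = np.random.default_rng(44)
        anchor = set(rng.choice(ids, 10, replace=False))
        db = _conditions_from_sets(
            [(f"c{i}", set(rng.choice(ids, 5, replace=False))) for i in range(8)]
        )
        null = anchored_null(m, anchor, db)
        assert [p[1] for p in null.pairs] == [c.name for c in db]
        for c, value in zip(db, null.values):
            assert value == set_distance(m, anchor, c.effectors).pooled_mean

    def test_condition_percentiles_are_ranks(self, small_store):
        """Against its own anchored reference, each condition's percentile
        is its rank over the condition count (a calibrated, uniform-on-grid
        ECDF)."""
        store, _ = small_store
        m = store.universe
        ids = sorted(m.node_ids)
        rng = np.random.default_rng(45)
        anchor = set(rng.choice(ids, 10, replace=False))
        db = _conditions_from_sets(
            [(f"c{i}", set(rng.choice(ids, 5, replace=False))) for i in range(9)]
        )
        null = anchored_null(m, anchor, db)
        pcts = sorted(percentile_of(null, d) for d in null.values)
        n = len(null.values)
        if len(set(null.values)) == n:  # no ties: exactly i/n
            assert pcts == pytest.approx([(i + 1) / n for i in range(n)])

    def test_empty_anchor_rejected(self, path5):
        db = _conditions_from_sets([("c1", {"v1"}), ("c2", {"v2"})])
        with pytest.raises(ValueError, match="empty node set"):
            anchored_null(path5, set(), db)


class TestPercentileOf:
    def _null(self, values):
        return NullDistribution(np.asarray(values, float),
                                [("a", "b")] * len(values), "pooled_mean")

    def test_support_edges_and_hand_count(self):
        null = self._null([1.0, 2.0, 3.0, 4.0])
        assert percentile_of(null, 0.5) == 0.0
        assert percentile_of(null, 4.0) == 1.0
        assert percentile_of(null, 2.0) == 0.5  # closed comparison: {1,2} of 4

    def test_nondecreasing_and_saturates(self):
        rng = np.random.default_rng(2)
        null = self._null(rng.normal(2.3, 0.5, size=200))
        grid = np.linspace(0, 5, 101)
        vals = [percentile_of(null, d) for d in grid]
        assert all(x <= y for x, y in zip(vals, vals[1:]))
        assert percentile_of(null, null.mean + 10 * null.sd) == 1.0

    def test_normal_fit_kind_uses_moments(self):
        null = self._null([2.0, 2.5, 3.0])
        from scipy.stats import norm

        assert percentile_of(null, 2.2, kind="normal") == pytest.approx(
            norm.cdf(2.2, loc=null.mean, scale=null.sd)
        )


class TestPathwayToMotiveDistances:
    def test_identity_and_adjacent_rows(self, path5):
        motives = [Motive("self", {"v1", "v2"}), Motive("next", {"v3"})]
        table = pathway_to_motive_distances(path5, {"pw": {"v1", "v2"}}, motives)
        by_motive = table.set_index("motive")
        assert by_motive.loc["self", "pooled_mean"] == 0.0
        assert by_motive.loc["self", "min_pairwise"] == 0
        assert by_motive.loc["next", "min_pairwise"] == 1

    def test_cells_equal_independent_set_distance_calls(self, small_store):
        store, _ = small_store
        m = store.universe
        ids = sorted(m.node_ids)
        rng = np.random.default_rng(9)
        pathways = {f"pw{i}": set(rng.choice(ids, 6, replace=False)) for i in range(2)}
        motives = [Motive(f"m{i}", set(rng.choice(ids, 4, replace=False))) for i in range(3)]
        table = pathway_to_motive_distances(m, pathways, motives)
        assert len(table) == 6
        for _, row in table.iterrows():
            sd = set_distance(m, pathways[row["pathway"]],
                              next(mm.effectors for mm in motives if mm.name == row["motive"]))
            assert row["pooled_mean"] == sd.pooled_mean
            assert row["min_pairwise"] == sd.min_pairwise
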