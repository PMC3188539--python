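import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lsckit import (
    InputError,
    QuartetConfig,
    build_contact_graph,
    clustering_permutation_test,
    clustering_statistic,
    consecutive_statistic,
    poisson_lrt,
    region_distribution_test,
    region_location_test,
    replicate_tree_rate_tests,
    select_quartet_sites,
)
from lsckit.core_io import StructureMap
from lsckit.synthetic import simulate_coordinates


def make_structmap(coords, columns=None):
    n = len(coords)
    columns = columns or list(range(1, n + 1))
    return StructureMap({c: i for i, c in enumerate(columns)}, coords)


def coords_from_xyz(xyz):
    from lsckit.core_io import ResidueCoordinates, ResidueRecord

    recs = [
        ResidueRecord("A", i + 1, " ", "A", np.asarray(p, float),
                      np.asarray([p], float))
        for i, p in enumerate(xyz)
    ]
    return ResidueCoordinates(recs)


class TestContactGraph:
    def test_simple_distances(self):
        coords = coords_from_xyz([(0, 0, 0), (3.8, 0, 0), (10, 0, 0)])
        sm = make_structmap(coords)
        g = build_contact_graph(sm, [1, 2, 3], threshold=4.0)
        assert set(g.nodes) == {1, 2, 3}
        assert sorted(g.edges) == [(1, 2)]

    def test_zero_threshold_no_edges(self):
        coords = coords_from_xyz([(0, 0, 0), (1, 0, 0)])
        g = build_contact_graph(make_structmap(coords), [1, 2], threshold=0.0)
        assert g.number_of_edges() == 0

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(8)
        xyz = rng.uniform(0, 15, size=(60, 3))
        coords = coords_from_xyz(xyz)
        sm = make_structmap(coords)
        cols = list(range(1, 61))
        g = build_contact_graph(sm, cols, threshold=4.0)
        brute = {
            (i + 1, j + 1)
            for i, j in itertools.combinations(range(60), 2)
            if np.linalg.norm(xyz[i] - xyz[j]) <= 4.0
        }
        assert {tuple(sorted(e)) for e in g.edges} == brute

    def test_unmapped_typed_columns_dropped(self):
        coords = coords_from_xyz([(0, 0, 0), (2, 0, 0)])
        sm = make_structmap(coords, columns=[1, 2])
        g = build_contact_graph(sm, [1, 2, 99], threshold=4.0)
        assert set(g.nodes) == {1, 2}


class TestQuartetSiteSelection:
    def _post(self, cols, values):
        return pd.DataFrame({"column": cols, "posterior": values})

    def test_disjoint_top_lists(self):
        p1 = self._post(range(1, 11), np.linspace(1, 0.1, 10))
        p2 = self._post(range(11, 21), np.linspace(1, 0.1, 10))
        e1, e2 = select_quartet_sites(p1, p2, n_sites=5)
        assert e1 == [1, 2, 3, 4, 5]
        assert e2 == [11, 12, 13, 14, 15]

    def test_common_sites_discarded_from_both(self):
        p1 = self._post([1, 2, 3, 4], [0.9, 0.8, 0.7, 0.1])
        p2 = self._post([3, 5, 6, 1], [0.9, 0.8, 0.7, 0.05])
        e1, e2 = select_quartet_sites(p1, p2, n_sites=3)
        assert e1 == [1, 2] and e2 == [5, 6]  # 3 was common

    def test_identical_top_lists_rejected(self):
        p = self._post([1, 2, 3], [0.9, 0.8, 0.7])
        with pytest.raises(InputError, match="empty"):
            select_quartet_sites(p, p.copy(), n_sites=3)

    def test_too_few_sites_rejected(self):
        p = self._post([1, 2], [0.9, 0.8])
        with pytest.raises(InputError, match="callable"):
            select_quartet_sites(p, p.copy(), n_sites=25)


class TestClusteringStatistics:
    def test_worked_example(self):
        g = nx.Graph([(1, 2), (5, 6)])
        assert clustering_statistic([1, 2], [5, 9], g) == 1

    def test_no_edges_zero(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2, 5, 9])
        assert clustering_statistic([1, 2], [5, 9], g) == 0

    def test_consecutive_pairs(self):
        coords = simulate_coordinates(20)
        sm = make_structmap(coords)
        assert consecutive_statistic([10, 11], [1, 5], sm) == 1
        assert consecutive_statistic([10, 12], [1, 5], sm) == 0


class TestPermutationTest:
    def test_exact_worked_fixture(self):
        g = nx.Graph([(1, 2), (5, 6)])
        res = clustering_permutation_test([1, 2], [5, 6], g)
        assert res.mode == "exact"
        assert res.statistic == 2
        assert res.p_value == pytest.approx(2 / 6)

    def test_zero_statistic_p_one(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2, 5, 6])
        res = clustering_permutation_test([1, 2], [5, 6], g)
        assert res.statistic == 0 and res.p_value == 1.0

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(4)
        xyz = rng.uniform(0, 8, size=(12, 3))
        g = build_contact_graph(make_structmap(coords_from_xyz(xyz)),
                                list(range(1, 13)), threshold=4.0)
        e1, e2 = list(range(1, 7)), list(range(7, 13))
        exact = clustering_permutation_test(e1, e2, g, QuartetConfig(seed=0))
        mc = clustering_permutation_test(
            e1, e2, g, QuartetConfig(n_perm=100_000, seed=1, exact_threshold=2)
        )
        assert exact.mode == "exact" and mc.mode == "monte-carlo"
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / mc.n_perm)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 1 / mc.n_perm

    def test_seed_reproducibility(self):
        g = nx.Graph([(i, i + 1) for i in range(1, 20)])
        cfg = QuartetConfig(n_perm=5000, seed=7, exact_threshold=2)
        e1, e2 = list(range(1, 11)), list(range(11, 21))
        r1 = clustering_permutation_test(e1, e2, g, cfg)
        r2 = clustering_permutation_test(e1, e2, g, cfg)
        assert r1.p_value == r2.p_value

    def test_overlapping_sets_rejected(self):
        g = nx.Graph()
        with pytest.raises(InputError, match="disjoint"):
            clustering_permutation_test([1, 2], [2, 3], g)


class TestRegionTests:
    def test_exact_worked_fixture(self):
        counts = np.array([0, 0, 5, 5, 5, 5], dtype=float)
        p = region_location_test(counts, [1, 2])
        assert p == pytest.approx(1 / 15)

    def test_constant_counts_rank_p_one(self):
        counts = np.full(8, 3.0)
        p = region_distribution_test(counts, [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_region_covering_everything_rejected(self):
        with pytest.raises(InputError, match="strictly inside"):
            region_location_test(np.arange(4.0), [1, 2, 3, 4])

    def test_unextreme_region_p_moderate(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(5, size=60).astype(float)
        region = list(rng.choice(np.arange(1, 61), size=10, replace=False))
        p = region_location_test(counts, region, n_resample=5000, seed=3)
        assert 0.01 < p <= 1.0

    def test_distribution_test_matches_exhaustive(self):
        counts = np.array([1.0, 2.0, 2.0, 7.0, 8.0, 9.0])
        from scipy.stats import rankdata

        ranks = rankdata(counts)
        obs = ranks[:2].sum()
        exhaustive = [
            ranks[list(c)].sum()
            for c in itertools.combinations(range(6), 2)
        ]
        expected = np.mean([s <= obs + 1e-9 for s in exhaustive])
        assert region_distribution_test(counts, [1, 2]) == pytest.approx(expected)


class TestPoissonLRT:
    def test_symmetric_counts_no_signal(self):
        res = poisson_lrt([5, 5], [1, 1])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_value(self):
        res = poisson_lrt([10, 0], [1, 1])
        assert res.statistic == pytest.approx(20 * np.log(2), abs=1e-9)
        assert res.df == 1
        assert res.p_value == pytest.approx(1.97e-4, rel=0.01)

    def test_three_tree_value(self):
        res = poisson_lrt([8, 12, 10], [1, 1, 1])
        expected = 2 * sum(x * np.log(x / 10) for x in (8, 12, 10))
        assert res.statistic == pytest.approx(expected)
        assert res.statistic == pytest.approx(0.805, abs=0.005)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.669, abs=0.005)

    def test_all_zero_counts(self):
        res = poisson_lrt([0, 0, 0], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_invariant_under_time_rescaling(self):
        x = [4, 9, 2, 14]
        t = [1.0, 2.0, 0.5, 3.0]
        a = poisson_lrt(x, t)
        b = poisson_lrt(x, [7.3 * v for v in t])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-9)

    def test_h0_calibration_small(self):
        # 2000 null replicates at lambda*t = 20 per tree; alpha 0.05
        rng = np.random.default_rng(17)
        x = rng.poisson(20.0, size=(2000, 2))
        rejections = sum(
            poisson_lrt(row, [1.0, 1.0]).p_value < 0.05 for row in x
        )
        assert 0.03 <= rejections / 2000 <= 0.07


class TestReplicateTests:
    def test_identical_replicates_p_one(self):
        sub_x = {"r1": 30.0, "r2": 30.0, "r3": 30.0}
        sub_t = {"r1": 2.0, "r2": 2.0, "r3": 2.0}
        stem_x = {"r1": 5.0, "r2": 5.0, "r3": 5.0}
        stem_t = {"r1": 1.0, "r2": 1.0, "r3": 1.0}
        a, b = replicate_tree_rate_tests(sub_x, sub_t, stem_x, stem_t)
        assert a.p_value == pytest.approx(1.0)
        assert b.p_value == pytest.approx(1.0)

    def test_fast_subtree_detected(self):
        rng = np.random.default_rng(2)
        t = 50.0
        sub_x = {"r1": float(rng.poisson(t)), "r2": float(rng.poisson(t)),
                 "r3": float(rng.poisson(3 * t))}
        sub_t = {k: t for k in sub_x}
        stem = {k: 1.0 for k in sub_x}
        a, _ = replicate_tree_rate_tests(sub_x, sub_t, stem, stem)
        assert a.p_value < 0.01

    def test_membership_mismatch_rejected(self):
        with pytest.raises(InputError, match="mismatch"):
            replicate_tree_rate_tests({"a": 1}, {"b": 1}, {"a": 1}, {"a": 1})
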