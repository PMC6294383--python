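"""Centroid interpolation and the spatial-clustering permutation test."""
import itertools

import numpy as np
import pandas as pd
import pytest

from cooccurnet import (CentroidTable, Partition, UnitCentroidTable,
                        interpolate_centroid, mean_distance_ratio,
                        spatial_permutation_test, species_centroids)
from cooccurnet.errors import AmongGroupsImpossibleError, NoWithinPairsError


def units_of(coords):
    return UnitCentroidTable(
        tuple(f"u{i}" for i in range(len(coords))), np.asarray(coords, float)
    )


class TestInterpolation:
    def test_mean_of_three(self):
        u = units_of([(0, 0), (2, 0), (1, 3)])
        assert interpolate_centroid(u, ["u0", "u1", "u2"]) == (1.0, 1.0)

    def test_single_unit_identity(self):
        u = units_of([(4.5, -2.0), (0, 0)])
        assert interpolate_centroid(u, ["u0"]) == (4.5, -2.0)

    def test_unknown_unit(self):
        u = units_of([(0, 0)])
        with pytest.raises(KeyError):
            interpolate_centroid(u, ["nope"])
        with pytest.raises(ValueError):
            interpolate_centroid(u, [])

    def test_random_occupancy_matches_mean(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(50, 2))
        u = units_of(coords)
        occupied = [f"u{i}" for i in sorted(rng.choice(50, 17, replace=False))]
        x, y = interpolate_centroid(u, occupied)
        idx = [int(s[1:]) for s in occupied]
        np.testing.assert_allclose([x, y], coords[idx].mean(axis=0))


class TestSpeciesCentroids:
    def test_disjoint_single_units(self):
        u = units_of([(1, 2), (3, 4)])
        occ = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"], columns=["u0", "u1"])
        c = species_centroids(u, occ)
        np.testing.assert_allclose(c.coords, [(1, 2), (3, 4)])

    def test_full_occupancy_is_overall_mean(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(10, 2))
        u = units_of(coords)
        occ = pd.DataFrame([[1] * 10], index=["a"], columns=[f"u{i}" for i in range(10)])
        c = species_centroids(u, occ)
        np.testing.assert_allclose(c.coords[0], coords.mean(axis=0))

    def test_species_without_units_excluded(self, caplog):
        u = units_of([(0, 0)])
        occ = pd.DataFrame([[1], [0]], index=["a", "b"], columns=["u0"])
        with caplog.at_level("WARNING"):
            c = species_centroids(u, occ)
        assert c.species_ids == ("a",)
        assert any("missing centroid" in r.message for r in caplog.records)

    def test_large_sample_near_group_mean(self):
        from cooccurnet.synth import (SyntheticConfig, generate_centroid_tables,
                                      generate_occurrences)
        cfg = SyntheticConfig(n_sites=40, species_per_group=3,
                              n_units_per_species=200, sigma_km=10.0, seed=4)
        m, truth = generate_occurrences(cfg)
        units, occ = generate_centroid_tables(cfg, truth)
        c = species_centroids(units, occ)
        means = np.asarray(truth.group_centroid_means)
        for sp, xy in zip(c.species_ids, c.coords):
            mu = means[truth.partition.assignment[sp] - 1]
            # sample mean of 200 draws at sigma=10: s.e. ~0.7 km per axis
            assert np.linalg.norm(xy - mu) < 3.5


def two_group_table():
    c = CentroidTable(("a", "b", "c", "d"),
                      np.array([(0, 0), (0, 1), (10, 0), (10, 1)], float))
    p = Partition.from_labels(["a", "b", "c", "d"], [1, 1, 2, 2])
    return c, p


class TestMeanDistanceRatio:
    def test_hand_computed_example(self):
        c, p = two_group_table()
        res = mean_distance_ratio(c, p)
        assert res.md_within == pytest.approx(1.0)
        expect_among = (10 + np.sqrt(101) + np.sqrt(101) + 10) / 4
        assert res.md_among == pytest.approx(expect_among)
        assert res.ratio == pytest.approx(1.0 / expect_among)

    def test_stacked_groups_ratio_zero(self):
        c = CentroidTable(("a", "b", "c", "d"),
                          np.array([(0, 0), (0, 0), (5, 5), (5, 5)], float))
        p = Partition.from_labels(["a", "b", "c", "d"], [1, 1, 2, 2])
        res = mean_distance_ratio(c, p)
        assert res.md_within == 0.0
        assert res.ratio == 0.0

    def test_k1_impossible(self):
        c = CentroidTable(("a", "b"), np.array([(0, 0), (1, 1)], float))
        p = Partition.from_labels(["a", "b"], [1, 1])
        with pytest.raises(AmongGroupsImpossibleError):
            mean_distance_ratio(c, p)

    def test_all_singletons_error(self):
        c = CentroidTable(("a", "b"), np.array([(0, 0), (1, 1)], float))
        p = Partition.from_labels(["a", "b"], [1, 2])
        with pytest.raises(NoWithinPairsError):
            mean_distance_ratio(c, p)

    def test_pair_accounting(self):
        rng = np.random.default_rng(3)
        n = 12
        c = CentroidTable(tuple(f"s{i}" for i in range(n)), rng.normal(size=(n, 2)))
        labels = [1 + i % 3 for i in range(n)]
        p = Partition.from_labels(list(c.species_ids), labels)
        from cooccurnet.spatial import _masks
        w, a = _masks(np.array(labels))
        assert w.sum() + a.sum() == n * (n - 1) // 2

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        n = 10
        coords = rng.normal(size=(n, 2)) * 5
        ids = tuple(f"s{i}" for i in range(n))
        p = Partition.from_labels(list(ids), [1 + i % 2 for i in range(n)])
        base = mean_distance_ratio(CentroidTable(ids, coords), p)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = coords @ rot.T + np.array([100.0, -40.0])
        res = mean_distance_ratio(CentroidTable(ids, moved), p)
        assert res.md_within == pytest.approx(base.md_within)
        assert res.md_among == pytest.approx(base.md_among)
        assert res.ratio == pytest.approx(base.ratio)

    def test_random_relabeling_ratio_near_one(self):
        rng = np.random.default_rng(5)
        n = 16
        ids = tuple(f"s{i}" for i in range(n))
        c = CentroidTable(ids, rng.normal(size=(n, 2)))
        ratios = []
        for _ in range(300):
            labels = rng.permutation([1 + i % 2 for i in range(n)])
            p = Partition.from_labels(list(ids), [int(x) for x in labels])
            ratios.append(mean_distance_ratio(c, p).ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)


class TestPermutationTest:
    def test_exhaustive_small_case(self):
        """6 species in 2 groups of 3: Monte-Carlo p matches the exact
        permutation distribution over all 6!/(3!3!) label arrangements."""
        rng = np.random.default_rng(11)
        ids = tuple(f"s{i}" for i in range(6))
        c = CentroidTable(ids, rng.normal(size=(6, 2)))
        labels = np.array([1, 1, 1, 2, 2, 2])
        p = Partition.from_labels(list(ids), labels.tolist())
        obs = mean_distance_ratio(c, p).ratio
        stats = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.full(6, 2)
            lab[list(combo)] = 1
            pp = Partition.from_labels(list(ids), lab.tolist())
            stats.append(mean_distance_ratio(c, pp).ratio)
        exact_p = np.mean([s <= obs + 1e-12 for s in stats])
        mc = spatial_permutation_test(c, p, n_perm=999, seed=0)
        se = np.sqrt(exact_p * (1 - exact_p) / 999)
        assert abs(mc.p - exact_p) <= 3 * se + 2 / 1000

    def test_planted_separation_strong_signal(self):
        rng = np.random.default_rng(21)
        ids = tuple(f"s{i}" for i in range(18))
        means = {1: (0, 0), 2: (50, 0), 3: (25, 43)}
        labels = [1 + i % 3 for i in range(18)]
        coords = np.array([rng.normal(means[l], 10.0) for l in labels])
        p = Partition.from_labels(list(ids), labels)
        res = spatial_permutation_test(CentroidTable(ids, coords), p,
                                       n_perm=999, seed=1)
        assert res.ratio < 1
        assert res.p <= 0.005

    def test_statistic_variants_run(self):
        c, p = two_group_table()
        for stat in ("ratio", "delta", "literal"):
            res = spatial_permutation_test(c, p, n_perm=49, seed=0, statistic=stat)
            assert 0 < res.p <= 1
            assert res.statistic == stat

    def test_literal_rule_uninformative_under_clustering(self):
        # the literal rule counts MD_within >= MD_among among permutations,
        # which stays near 0.5-1 even for strong clustering
        c, p = two_group_table()
        res = spatial_permutation_test(c, p, n_perm=199, seed=0, statistic="literal")
        assert res.p > 0.2

    def test_deterministic(self):
        c, p = two_group_table()
        a = spatial_permutation_test(c, p, n_perm=99, seed=5)
        b = spatial_permutation_test(c, p, n_perm=99, seed=5)
        assert a == b

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(77)
        n = 18
        ids = tuple(f"s{i}" for i in range(n))
        labels = [1 + i % 3 for i in range(n)]
        reject = 0
        n_rep = 200
        for _ in range(n_rep):
            coords = rng.normal(size=(n, 2))
            p = Partition.from_labels(list(ids), labels)
            res = spatial_permutation_test(CentroidTable(ids, coords), p,
                                           n_perm=199, seed=int(rng.integers(2**31)))
            reject += res.p <= 0.05
        assert 0.02 <= reject / n_rep <= 0.09
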