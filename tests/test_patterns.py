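"""Twice-clustering, elbow selection, and the DFCP feature constructions."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from dfcp import (
    ClusteringParams,
    DfcpModel,
    DfcpWarning,
    Wqcp,
    assign_pattern,
    beta_regress,
    dfcp_features,
    elbow_select,
    mean_beta,
    ratio_features,
    twice_cluster,
)
from conftest import random_wqcps


def make_model(centroids, seed=0):
    centroids = np.asarray(centroids, dtype=float)
    return DfcpModel(
        centroids=centroids,
        kmeans_k0=centroids.shape[1],
        linkage="ward",
        k_candidates=(),
        elbow_curve=np.array([]),
        random_seed=seed,
    )


class TestElbow:
    def test_knee_on_steep_then_flat_curve(self):
        assert elbow_select([100, 20, 18, 17, 16], candidates=[1, 2, 3, 4, 5]) == 2

    def test_linear_curve_ties_to_smallest_candidate(self):
        assert elbow_select([50, 40, 30, 20, 10], candidates=[2, 3, 4, 5, 6]) == 2

    def test_short_curve_returns_argmin(self):
        assert elbow_select([5.0, 3.0], candidates=[2, 3]) == 3


class TestTwiceCluster:
    def test_recovers_three_separated_blobs(self, rng):
        centers = [np.zeros(8), np.full(8, 10.0), np.r_[np.full(4, -10.0), np.zeros(4)]]
        wqcps, labels = random_wqcps(rng, 90, 8, centers=centers, spread=1.0)
        model = twice_cluster(
            wqcps, ClusteringParams(k_candidates=tuple(range(2, 9)), random_seed=3)
        )
        assert model.K == 3
        predicted = [assign_pattern(w, model) for w in wqcps]
        assert adjusted_rand_score(labels, predicted) == 1.0

    def test_identical_wqcps_collapse_to_smallest_candidate(self, rng):
        wqcps = [
            Wqcp(values=np.full(5, 2.0), window_span=(i, i + 1)) for i in range(20)
        ]
        model = twice_cluster(
            wqcps, ClusteringParams(k_candidates=(2, 3, 4), random_seed=0)
        )
        assert model.K == 2
        np.testing.assert_allclose(model.centroids, np.full((5, 2), 2.0))

    def test_input_order_invariance_up_to_permutation(self, rng):
        centers = [np.zeros(6), np.full(6, 8.0)]
        wqcps, _ = random_wqcps(rng, 60, 6, centers=centers)
        params = ClusteringParams(k_candidates=(2, 3, 4), random_seed=11)
        m1 = twice_cluster(wqcps, params)
        shuffled = list(wqcps)
        rng.shuffle(shuffled)
        m2 = twice_cluster(shuffled, params)
        assert m1.K == m2.K
        c1 = sorted(map(tuple, np.round(m1.centroids.T, 9)))
        c2 = sorted(map(tuple, np.round(m2.centroids.T, 9)))
        np.testing.assert_allclose(c1, c2, atol=1e-7)

    def test_oversized_k0_is_lowered_with_warning(self, rng):
        wqcps, _ = random_wqcps(rng, 8, 4)
        with pytest.warns(DfcpWarning, match="lowering"):
            model = twice_cluster(
                wqcps, ClusteringParams(kmeans_k0=20, k_candidates=(2, 3), random_seed=0)
            )
        assert model.kmeans_k0 == 8

    def test_elbow_curve_is_recorded_per_candidate(self, rng):
        wqcps, _ = random_wqcps(rng, 40, 5, centers=[np.zeros(5), np.full(5, 9.0)])
        model = twice_cluster(wqcps, ClusteringParams(k_candidates=(2, 3, 4, 5), random_seed=1))
        assert len(model.elbow_curve) == len(model.k_candidates) == 4

    def test_planted_recovery_rate_across_seeds(self):
        """Separation 10 sigma: planted K and labels recovered in >= 95/100 seeds."""
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            centers = [np.zeros(6), np.full(6, 10.0), np.r_[np.full(3, 10.0), np.full(3, -10.0)]]
            wqcps, labels = random_wqcps(rng, 75, 6, centers=centers, spread=1.0)
            model = twice_cluster(
                wqcps, ClusteringParams(k_candidates=tuple(range(2, 9)), random_seed=seed)
            )
            if model.K != 3:
                continue
            pred = [assign_pattern(w, model) for w in wqcps]
            ok += adjusted_rand_score(labels, pred) >= 0.9
        assert ok >= 95


class TestBetaRegression:
    def test_exact_centroid_gives_unit_coefficient(self, rng):
        R = rng.standard_normal((10, 3))
        model = make_model(R)
        w = Wqcp(values=R[:, 0], window_span=(0, 1))
        np.testing.assert_allclose(beta_regress(w, model), [1, 0, 0], atol=1e-10)

    def test_in_span_mixture_recovered(self, rng):
        R = rng.standard_normal((10, 3))
        model = make_model(R)
        w = Wqcp(values=0.5 * R[:, 0] + 0.5 * R[:, 1], window_span=(0, 1))
        np.testing.assert_allclose(beta_regress(w, model), [0.5, 0.5, 0.0], atol=1e-10)

    def test_matches_normal_equations_and_residual_orthogonality(self, rng):
        R = rng.standard_normal((12, 4))
        model = make_model(R)
        v = rng.standard_normal(12)
        beta = beta_regress(Wqcp(values=v, window_span=(0, 1)), model)
        expected = np.linalg.solve(R.T @ R, R.T @ v)
        np.testing.assert_allclose(beta, expected, atol=1e-10)
        residual = v - R @ beta
        np.testing.assert_allclose(R.T @ residual, np.zeros(4), atol=1e-8)

    def test_rank_deficient_centroids_use_minimum_norm(self, rng):
        col = rng.standard_normal(8)
        R = np.column_stack([col, col])  # duplicated pattern
        model = make_model(R)
        beta = beta_regress(Wqcp(values=2.0 * col, window_span=(0, 1)), model)
        np.testing.assert_allclose(beta, [1.0, 1.0], atol=1e-10)  # min-norm split

    def test_in_span_reconstruction_error_tiny(self, rng):
        R = rng.standard_normal((10, 3))
        model = make_model(R)
        coeffs = rng.standard_normal(3)
        w = Wqcp(values=R @ coeffs, window_span=(0, 1))
        beta = beta_regress(w, model)
        assert np.linalg.norm(R @ beta - w.values) < 1e-8


class TestAssignment:
    def test_centroid_assigns_to_itself(self, rng):
        R = rng.standard_normal((7, 5))
        model = make_model(R)
        for k in range(5):
            assert assign_pattern(Wqcp(values=R[:, k], window_span=(0, 1)), model) == k

    def test_equidistant_tie_goes_to_lowest_index(self):
        R = np.array([[1.0, -1.0], [0.0, 0.0]])
        model = make_model(R)
        assert assign_pattern(Wqcp(values=np.zeros(2), window_span=(0, 1)), model) == 0

    def test_matches_brute_force_argmin(self, rng):
        R = rng.standard_normal((9, 5))
        model = make_model(R)
        for _ in range(20):
            v = rng.standard_normal(9)
            expected = int(
                np.argmin([np.sum((v - R[:, k]) ** 2) for k in range(5)])
            )
            assert assign_pattern(Wqcp(values=v, window_span=(0, 1)), model) == expected


class TestFeatures:
    def test_ratio_concentration(self):
        np.testing.assert_array_equal(ratio_features([0] * 5, K=4), [1, 0, 0, 0])

    def test_ratio_counting(self):
        np.testing.assert_allclose(ratio_features([0, 0, 1, 2], K=3), [0.5, 0.25, 0.25])

    def test_ratios_sum_to_one(self, rng):
        for _ in range(20):
            a = rng.integers(0, 6, size=rng.integers(1, 30))
            assert ratio_features(a, K=6).sum() == pytest.approx(1.0)

    def test_zero_wqcps_flagged_zero_vector(self):
        with pytest.warns(DfcpWarning):
            r = ratio_features([], K=4)
        np.testing.assert_array_equal(r, np.zeros(4))

    def test_mean_beta_of_one_is_itself(self, rng):
        b = rng.standard_normal(4)
        np.testing.assert_array_equal(mean_beta([b]), b)

    def test_mean_beta_symmetry(self):
        np.testing.assert_allclose(
            mean_beta([np.array([1.0, 0.0]), np.array([0.0, 1.0])]), [0.5, 0.5]
        )

    def test_mean_beta_matches_arithmetic_mean(self, rng):
        betas = [rng.standard_normal(5) for _ in range(10)]
        np.testing.assert_allclose(mean_beta(betas), np.mean(betas, axis=0), atol=1e-12)

    def test_subject_concentrated_on_one_pattern(self, rng):
        R = rng.standard_normal((8, 3))
        model = make_model(R)
        wqcps = [Wqcp(values=R[:, 1], window_span=(i, i + 1)) for i in range(6)]
        fv = dfcp_features(wqcps, model, "s", "case")
        np.testing.assert_allclose(fv.ratios, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(fv.mean_betas, [0, 1, 0], atol=1e-8)

    def test_planted_occupancy_recovered_from_fifty_wqcps(self):
        """Occupancy (0.7, 0.3) over well-separated states: ratios within 0.1."""
        rng = np.random.default_rng(5)
        centers = [np.zeros(10), np.full(10, 8.0)]
        labels = (rng.random(50) < 0.3).astype(int)  # ~0.7 / 0.3 split
        wqcps = [
            Wqcp(values=centers[k] + 0.5 * rng.standard_normal(10), window_span=(i, i + 1))
            for i, k in enumerate(labels)
        ]
        model = twice_cluster(wqcps, ClusteringParams(random_seed=0))
        fv = dfcp_features(wqcps, model, "s", "case")
        target = np.bincount(labels, minlength=2) / 50
        assert model.K == 2
        assert np.abs(np.sort(fv.ratios) - np.sort(target)).max() <= 0.1
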