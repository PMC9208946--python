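"""Fuzzy C-means core: closed-form updates against hand-derived values,
alternating-minimisation guarantees, PSO initialisation, and Jaccard scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cluster import KMeans

from neurofuzz import (
    FCMConfig,
    PSOConfig,
    defuzzify,
    fcm_objective,
    fcm_segment,
    jaccard_similarity,
    per_class_jaccard,
    pso_init_centers,
    update_centers,
    update_membership,
)


class TestObjective:
    def test_zero_at_centers_with_crisp_membership(self):
        data = np.array([0.0, 10.0])
        u = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert fcm_objective(data, [0.0, 10.0], u, m=2.0) == 0.0

    def test_hand_summed_single_center(self):
        # both points at squared distance 25 from center 5, full membership
        data = np.array([0.0, 10.0])
        u = np.ones((1, 2))
        assert fcm_objective(data, [5.0], u, m=2.0) == pytest.approx(50.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fcm_objective(np.arange(3.0), [0.0, 1.0], np.ones((2, 2)))


class TestMembershipUpdate:
    def test_point_at_center_gets_crisp_membership(self):
        u = update_membership(np.array([0.0, 10.0]), [0.0, 10.0], m=2.0)
        assert np.allclose(u.values, np.eye(2))

    def test_equidistant_point_splits_evenly(self):
        u = update_membership(np.array([5.0]), [0.0, 10.0], m=2.0)
        assert np.allclose(u.values[:, 0], [0.5, 0.5])

    def test_hand_evaluated_ratio(self):
        # d_near=2, d_far=8: u_near = 1/(1+(2/8)^2) = 16/17
        u = update_membership(np.array([2.0]), [0.0, 10.0], m=2.0)
        assert abs(u.values[0, 0] - 16.0 / 17.0) < 1e-12

    def test_identical_centers_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            update_membership(np.arange(4.0), [3.0, 3.0], m=2.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.integers(2, 5),
        st.floats(1.2, 4.0),
    )
    def test_columns_always_sum_to_one(self, seed, n_clusters, m):
        rng = np.random.default_rng(seed)
        data = rng.uniform(0, 255, size=50)
        centers = rng.uniform(0, 255, size=n_clusters)
        centers += np.arange(n_clusters) * 1e-6  # keep centers distinct
        u = update_membership(data, centers, m=m)
        assert np.abs(u.values.sum(axis=0) - 1.0).max() <= 1e-9
        assert (u.values >= 0).all() and (u.values <= 1).all()


class TestCenterUpdate:
    def test_crisp_memberships_give_class_means(self):
        data = np.array([0.0, 2.0, 10.0, 14.0])
        u = np.array([[1.0, 1, 0, 0], [0.0, 0, 1, 1]])
        assert np.allclose(update_centers(data, u, m=2.0).ravel(), [1.0, 12.0])

    def test_uniform_memberships_collapse_to_global_mean(self):
        data = np.array([0.0, 4.0, 8.0])
        u = np.full((2, 3), 0.5)
        assert np.allclose(update_centers(data, u, m=2.0).ravel(), [4.0, 4.0])

    def test_single_point(self):
        assert update_centers(np.array([7.0]), np.ones((1, 1)), m=2.0)[0, 0] == 7.0

    def test_zero_mass_cluster_rejected(self):
        u = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="zero membership"):
            update_centers(np.array([1.0, 2.0]), u, m=2.0)


class TestDefuzzify:
    def test_argmax_and_tie_rule(self):
        u = np.array([[1.0, 0.5, 0.2], [0.0, 0.5, 0.3], [0.0, 0.0, 0.5]])
        assert defuzzify(u).tolist() == [0, 0, 2]


class TestJaccard:
    def test_identity_disjoint_and_partial(self):
        a = np.zeros((3, 3), dtype=bool)
        a[0] = True
        assert jaccard_similarity(a, a) == 1.0
        assert jaccard_similarity(a, ~a) == 0.0
        # |intersection|=3, |union|=9
        b = np.zeros((3, 3), dtype=bool)
        b[0] = True
        c = np.ones((3, 3), dtype=bool)
        assert jaccard_similarity(b, c) == pytest.approx(1.0 / 3.0)

    def test_empty_convention_and_shape_check(self):
        empty = np.zeros((2, 2), dtype=bool)
        assert jaccard_similarity(empty, empty) == 1.0
        with pytest.raises(ValueError):
            jaccard_similarity(empty, np.zeros((3, 3), dtype=bool))


class TestPSO:
    def test_gbest_trace_monotone_and_deterministic(self, phantom3):
        _, image, _ = phantom3
        cfg = PSOConfig(n_particles=10, n_pso_iter=15, seed=3)
        a = pso_init_centers(image.ravel(), 3, cfg)
        b = pso_init_centers(image.ravel(), 3, cfg)
        assert np.array_equal(a.centers, b.centers)
        assert all(x >= y for x, y in zip(a.gbest_trace, a.gbest_trace[1:]))

    def test_two_blob_recovery_matches_grid_oracle(self):
        rng = np.random.default_rng(0)
        data = np.concatenate([rng.normal(0, 1, 100), rng.normal(100, 1, 100)])
        result = pso_init_centers(data, 2, PSOConfig(seed=1))
        found = np.sort(result.centers.ravel())

        # independent oracle: exhaustive grid search over center pairs
        def implied_J(c):
            d = np.abs(data[None, :] - np.asarray(c)[:, None])
            d = np.maximum(d, 1e-12)
            w = d**-2.0
            u = w / w.sum(axis=0)
            return float(np.sum(u**2 * d**2))

        grid = np.linspace(-3, 103, 54)
        pairs = [(a, b) for i, a in enumerate(grid) for b in grid[i + 1:]]
        best = min(pairs, key=implied_J)
        assert abs(found[0] - 0.0) < 1.0 and abs(found[1] - 100.0) < 1.0
        assert abs(best[0] - 0.0) < 1.5 and abs(best[1] - 100.0) < 1.5
        assert implied_J(found) <= implied_J(best) * 1.001

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            pso_init_centers(np.array([1.0, 1.0, 2.0]), 3, PSOConfig(seed=0))


class TestSegmentation:
    def test_noiseless_two_class_matches_threshold_oracle(self, phantom2_noiseless):
        _, image, truth = phantom2_noiseless
        result = fcm_segment(image, FCMConfig(n_clusters=2), init="pso", seed=0)
        oracle = (image > 120.0).astype(int)  # midpoint threshold
        assert np.array_equal(oracle, truth)
        js = per_class_jaccard(result.label_map, truth)
        assert js == {0: 1.0, 1: 1.0}

    def test_iteration_cap_contract(self, phantom3):
        _, image, _ = phantom3
        cfg = FCMConfig(n_clusters=3, max_iter=1)
        result = fcm_segment(image, cfg, init="given",
                             initial_centers=[0.0, 100.0, 255.0])
        assert result.model.n_iter == 1
        assert not result.model.converged

    def test_objective_trace_non_increasing(self, rng):
        for _ in range(5):
            data = rng.uniform(0, 255, size=rng.integers(20, 200))
            result = fcm_segment(data, FCMConfig(n_clusters=3), init="random",
                                 seed=int(rng.integers(1000)))
            trace = result.model.objective_trace
            assert all(a >= b - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_permuting_initial_centers_only_permutes_labels(self, phantom3):
        _, image, _ = phantom3
        cfg = FCMConfig(n_clusters=3)
        a = fcm_segment(image, cfg, init="given",
                        initial_centers=[10.0, 100.0, 240.0])
        b = fcm_segment(image, cfg, init="given",
                        initial_centers=[240.0, 10.0, 100.0])
        # canonical ascending-center ordering makes the outputs identical
        assert np.array_equal(a.label_map, b.label_map)
        assert np.allclose(np.sort(a.model.centers), np.sort(b.model.centers))

    def test_matches_kmeans_oracle_on_three_class_phantom(self, phantom3):
        _, image, truth = phantom3
        result = fcm_segment(image, FCMConfig(n_clusters=3), init="pso", seed=2)
        km = KMeans(n_clusters=3, n_init=1,
                    init=np.array([[20.0], [120.0], [220.0]]))
        km_labels = km.fit_predict(image.reshape(-1, 1)).reshape(image.shape)
        order = np.argsort(km.cluster_centers_.ravel())
        km_labels = np.argsort(order)[km_labels]
        assert np.mean(result.label_map == km_labels) >= 0.99

    def test_membership_argmax_consistency(self, phantom3):
        _, image, _ = phantom3
        result = fcm_segment(image, FCMConfig(n_clusters=3), init="pso", seed=0)
        assert np.array_equal(
            result.label_map.ravel(), defuzzify(result.membership)
        )

    def test_invalid_init_and_center_counts(self, phantom3):
        _, image, _ = phantom3
        with pytest.raises(ValueError):
            fcm_segment(image, init="guess")
        with pytest.raises(ValueError):
            fcm_segment(image, FCMConfig(n_clusters=3), init="given",
                        initial_centers=[1.0, 2.0])
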