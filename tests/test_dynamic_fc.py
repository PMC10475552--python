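"""Sliding windows, windowed connectivity, k-means states, state contrasts."""

import numpy as np
import pytest

from dynstates.dynamic_fc import (StateModel, WindowSpec, cluster_states,
                                  group_centroids, make_windows, select_k,
                                  state_edge_ttest, top_edges, windowed_fc)
from dynstates.static_fc import vectorize_edges


class TestMakeWindows:
    @pytest.mark.parametrize("n, width, step, expected", [
        (120, 30, 1, 90),    # the study geometry
        (120, 40, 1, 80),    # robustness rerun geometry
        (31, 30, 1, 1),
        (120, 30, 2, 45),
    ])
    def test_window_counts(self, n, width, step, expected):
        windows = make_windows(n, WindowSpec(width, step))
        assert len(windows) == expected
        assert windows[0] == (0, width)
        assert all(b - a == width for a, b in windows)

    def test_width_too_large_rejected(self):
        with pytest.raises(ValueError):
            make_windows(30, WindowSpec(30, 1))


class TestWindowedFc:
    def test_stationary_series_windows_near_static_value(self, rng):
        cov = np.array([[1, 0.6], [0.6, 1]])
        tc = rng.multivariate_normal([0, 0], cov, size=2000)
        from dynstates.static_fc import static_matrix
        static = vectorize_edges(static_matrix(tc))
        W60 = windowed_fc(tc, make_windows(2000, WindowSpec(60, 60)))
        W300 = windowed_fc(tc, make_windows(2000, WindowSpec(300, 300)))
        dev60 = np.abs(W60 - static).mean()
        dev300 = np.abs(W300 - static).mean()
        assert dev300 < dev60            # deviation shrinks with width
        assert dev300 < 0.1

    def test_identical_components_clipped_every_window(self, rng):
        x = rng.standard_normal(100)
        tc = np.column_stack([x, x])
        W = windowed_fc(tc, make_windows(100, WindowSpec(30, 1)))
        assert np.all(W > 8)             # atanh clip value

    def test_two_state_windows_closer_to_own_state_vector(self):
        from dynstates.synthetic import CohortSpec, gen_component_timecourses
        spec = CohortSpec(n_group_a=2, n_group_b=2, noise_sd=0.0, ar_coeff=0.0)
        states = np.concatenate([np.ones(200, int), np.full(200, 2, int)])
        tc = gen_component_timecourses(states, spec, seed=3)
        iu = np.triu_indices(20, k=1)
        c1 = np.arctanh(spec.state_covariances[0][iu])
        c2 = np.arctanh(spec.state_covariances[1][iu])
        windows = make_windows(400, WindowSpec(30, 1))
        W = windowed_fc(tc, windows)
        pure1 = [w for w, (a, b) in enumerate(windows) if b <= 200]
        pure2 = [w for w, (a, b) in enumerate(windows) if a >= 200]
        for w in pure1:
            assert np.linalg.norm(W[w] - c1) < np.linalg.norm(W[w] - c2)
        for w in pure2:
            assert np.linalg.norm(W[w] - c2) < np.linalg.norm(W[w] - c1)


class TestSelectK:
    def _clouds(self, rng, k, n_per=120, dim=20, sep=8.0):
        centres = rng.standard_normal((k, dim)) * sep
        return np.vstack([c + rng.standard_normal((n_per, dim))
                          for c in centres])

    def test_two_separated_clouds(self, rng):
        X = self._clouds(rng, 2)
        k_opt, curve = select_k(X, range(2, 7), n_init=5, seed=1)
        assert k_opt == 2

    def test_three_separated_clouds(self, rng):
        X = self._clouds(rng, 3)
        k_opt, _ = select_k(X, range(2, 7), n_init=5, seed=2)
        assert k_opt == 3

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            select_k(np.ones((50, 4)), range(2, 4))


class TestClusterStates:
    def test_k_below_two_rejected(self, rng):
        W = rng.standard_normal((2, 30, 6))
        with pytest.raises(ValueError):
            cluster_states(W, k=1)

    def test_state_one_is_strongest(self, rng):
        lo = rng.standard_normal((1, 40, 6)) * 0.1
        hi = rng.standard_normal((1, 40, 6)) * 0.1 + 2.0
        model = cluster_states(np.concatenate([lo, hi]), 2, n_init=5, seed=0)
        assert model.centroids[0].mean() > model.centroids[1].mean()

    def test_duplicating_windows_preserves_centroids_and_fractions(self, rng):
        W = np.concatenate([rng.standard_normal((1, 30, 5)) * 0.2,
                            rng.standard_normal((1, 30, 5)) * 0.2 + 3.0])
        m1 = cluster_states(W, 2, n_init=10, seed=4)
        m2 = cluster_states(np.concatenate([W, W]), 2, n_init=10, seed=4)
        np.testing.assert_allclose(np.sort(m1.centroids, axis=0),
                                   np.sort(m2.centroids, axis=0), atol=1e-6)
        np.testing.assert_allclose(m1.occurrence, m2.occurrence, atol=1e-12)

    def test_occurrence_fractions_sum_to_one(self, rng):
        W = rng.standard_normal((4, 50, 8))
        model = cluster_states(W, 3, n_init=5, seed=5)
        assert model.occurrence.sum() == pytest.approx(1.0)
        assert model.assignments.min() >= 1
        assert model.assignments.max() <= 3

    def test_cityblock_distance_available(self, rng):
        lo = rng.standard_normal((1, 30, 4)) * 0.1
        hi = rng.standard_normal((1, 30, 4)) * 0.1 + 2.0
        model = cluster_states(np.concatenate([lo, hi]), 2, n_init=3, seed=6,
                               distance="cityblock")
        assert model.centroids[0].mean() > model.centroids[1].mean()


class TestGroupCentroids:
    def _single_state_model(self, assignments):
        k = int(assignments.max())
        return StateModel(k=k, centroids=np.zeros((k, 2)),
                          assignments=assignments,
                          occurrence=np.ones(k) / k, inertia=0.0)

    def test_single_subject_single_state(self, rng):
        W = rng.standard_normal((1, 10, 2))
        model = self._single_state_model(np.ones((1, 10), dtype=int))
        cents, counts = group_centroids(model, W, np.array(["patient"]))
        np.testing.assert_allclose(cents["patient"][0], W[0].mean(axis=0))
        assert counts["patient"][0] == 1

    def test_opposite_subjects_cancel(self):
        v = np.array([1.0, -2.0])
        W = np.stack([np.tile(v, (10, 1)), np.tile(-v, (10, 1))])
        model = self._single_state_model(np.ones((2, 10), dtype=int))
        cents, _ = group_centroids(model, W, np.array(["control", "control"]))
        np.testing.assert_allclose(cents["control"][0], 0.0, atol=1e-12)

    def test_unvisited_state_flagged_by_zero_count(self, rng):
        W = rng.standard_normal((2, 10, 2))
        assignments = np.ones((2, 10), dtype=int)
        model = StateModel(k=2, centroids=np.zeros((2, 2)),
                           assignments=assignments,
                           occurrence=np.array([1.0, 0.0]), inertia=0.0)
        cents, counts = group_centroids(model, W,
                                        np.array(["patient", "patient"]))
        assert counts["patient"][1] == 0
        assert np.isnan(cents["patient"][1]).all()


class TestStateEdgeTtest:
    def test_identical_groups_no_excess_significance(self, rng):
        W = rng.standard_normal((40, 30, 20)) * 0.3
        model = cluster_states(W, 2, n_init=5, seed=7)
        groups = np.repeat([0, 1], 20)
        res = state_edge_ttest(model, W, groups, alpha=0.01)
        for s, r in res.items():
            if not r["skipped"]:
                assert r["sig"].mean() < 0.08

    def test_planted_increase_detected_with_direction(self, rng):
        n_edge = 10
        base = rng.standard_normal((30, 40, n_edge)) * 0.2
        base[15:, :, 3] += 1.5          # patients higher on edge 3
        assignments = np.ones((30, 40), dtype=int)
        model = StateModel(k=1 + 1, centroids=np.zeros((2, n_edge)),
                           assignments=assignments,
                           occurrence=np.array([1.0, 0.0]), inertia=0.0)
        groups = np.repeat([0, 1], 15)
        res = state_edge_ttest(model, base, groups, alpha=0.01)
        r = res[1]
        assert bool(r["sig"][3])
        assert r["direction"][3] > 0


class TestTopEdges:
    def test_full_fraction_returns_all(self, rng):
        c = rng.standard_normal(20)
        assert len(top_edges(c, 1.0)) == 20

    def test_five_percent_of_190_is_10(self, rng):
        c = rng.standard_normal(190)
        te = top_edges(c, 0.05)
        assert len(te) == 10
        assert set(te) == set(np.argsort(-c)[:10])

    def test_decreasing_centroid_selects_prefix(self):
        c = np.linspace(5, 1, 40)
        np.testing.assert_array_equal(top_edges(c, 0.1), np.arange(4))


class TestRecoveryOnSyntheticCohort:
    def test_assignment_agreement_with_truth(self, small_cohort):
        """Window states recover majority-vote ground truth well above chance."""
        spec, man = small_cohort
        windows = make_windows(spec.n_kept, WindowSpec(30, 1))
        W = np.stack([windowed_fc(man["_timecourses"][sid][spec.n_discard:],
                                  windows)
                      for sid in man["subject_ids"]])
        model = cluster_states(W, 2, n_init=30, seed=8)
        truth = man["_truth_obj"]
        agree = np.mean([
            (model.assignments[i] == np.asarray(truth.window_labels[sid])).mean()
            for i, sid in enumerate(man["subject_ids"])])
        agree = max(agree, 1 - agree)
        assert agree > 0.8

    def test_group_b_state2_occupancy_ordering(self, tmp_path):
        """Patients occupy the weak state more than controls, as generated."""
        from dynstates.synthetic import CohortSpec, gen_cohort
        man = gen_cohort(CohortSpec(seed=42), tmp_path, write_images=False)
        truth = man["_truth_obj"]
        frac2 = {"patient": [], "control": []}
        for sid, grp in zip(truth.subject_ids, truth.groups):
            frac2[grp].append(truth.true_metrics[sid]["frac_s2"])
        assert np.mean(frac2["patient"]) > np.mean(frac2["control"])
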