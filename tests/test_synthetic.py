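"""Synthetic cohort generator: Markov states, state-dependent signals,
voxel mixing, motion traces and the on-disk cohort bundle."""

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pytest

from dynstates.motion import framewise_displacement
from dynstates.synthetic import (CohortSpec, default_state_covariances,
                                 gen_component_timecourses, gen_cohort,
                                 gen_motion_trace, gen_state_sequence,
                                 gen_voxel_images, make_mixing_maps,
                                 majority_vote_window_labels)


def tiny_spec(**kw):
    kw.setdefault("n_group_a", 2)
    kw.setdefault("n_group_b", 2)
    return CohortSpec(**kw)


class TestStateSequence:
    def test_absorbing_chain_is_constant(self):
        seq = gen_state_sequence(100, np.eye(2), seed=4)
        assert len(np.unique(seq)) == 1

    def test_symmetric_chain_stationary_fraction(self):
        n = 100_000
        seq = gen_state_sequence(n, [[0.9, 0.1], [0.1, 0.9]], seed=1)
        frac = (seq == 1).mean()
        # stationary 0.5; 3 standard errors allowing dependence inflation
        # (effective n shrinks by (1+p)/(1-p) = 19 for the run-correlated chain)
        se = np.sqrt(0.25 / (n / 19))
        assert abs(frac - 0.5) < 3 * se

    @pytest.mark.parametrize("p", [0.8, 0.9, 0.95])
    def test_mean_run_length_matches_geometric(self, p):
        seq = gen_state_sequence(100_000, [[p, 1 - p], [1 - p, p]], seed=2)
        change = np.flatnonzero(np.diff(seq) != 0)
        lengths = np.diff(np.concatenate([[0], change + 1, [len(seq)]]))
        assert np.mean(lengths) == pytest.approx(1 / (1 - p), rel=0.05)

    def test_empirical_transition_frequencies(self):
        tm = np.array([[0.85, 0.15], [0.05, 0.95]])
        seq = gen_state_sequence(100_000, tm, seed=3) - 1
        for s in (0, 1):
            at_s = np.flatnonzero(seq[:-1] == s)
            stay = (seq[at_s + 1] == s).mean()
            se = np.sqrt(tm[s, s] * (1 - tm[s, s]) / len(at_s))
            assert abs(stay - tm[s, s]) < 3 * se

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            gen_state_sequence(10, [[0.9, 0.2], [0.1, 0.9]], seed=0)

    def test_seed_reproducibility(self):
        a = gen_state_sequence(500, [[0.9, 0.1], [0.2, 0.8]], seed=9)
        b = gen_state_sequence(500, [[0.9, 0.1], [0.2, 0.8]], seed=9)
        np.testing.assert_array_equal(a, b)


class TestComponentTimecourses:
    def test_sample_covariance_matches_state_covariance(self):
        spec = tiny_spec(noise_sd=0.0, ar_coeff=0.0)
        states = np.ones(100_000, dtype=int)
        tc = gen_component_timecourses(states, spec, seed=5)
        np.testing.assert_allclose(np.cov(tc.T), spec.state_covariances[0],
                                   atol=0.02)

    def test_ar_coefficient_preserves_marginal_covariance(self):
        spec = tiny_spec(noise_sd=0.0)       # default ar_coeff 0.4
        states = np.full(100_000, 2, dtype=int)
        tc = gen_component_timecourses(states, spec, seed=6)
        np.testing.assert_allclose(np.cov(tc.T), spec.state_covariances[1],
                                   atol=0.02)

    def test_diagonal_covariance_gives_uncorrelated_components(self):
        spec = tiny_spec(noise_sd=0.0, ar_coeff=0.0,
                         state_covariances=(np.eye(20), np.eye(20) * 0.5))
        tc = gen_component_timecourses(np.ones(100_000, dtype=int), spec, seed=7)
        r = np.corrcoef(tc.T)
        np.fill_diagonal(r, 0)
        assert np.abs(r).max() < 0.02

    def test_seed_determinism(self):
        spec = tiny_spec()
        states = gen_state_sequence(130, [[0.9, 0.1], [0.1, 0.9]], seed=0)
        a = gen_component_timecourses(states, spec, seed=8)
        b = gen_component_timecourses(states, spec, seed=8)
        np.testing.assert_array_equal(a, b)

    def test_non_positive_definite_covariance_rejected(self):
        bad = np.full((20, 20), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99
        with pytest.raises(ValueError):
            tiny_spec(state_covariances=(bad, np.eye(20)))


class TestDefaultCovariances:
    def test_block_structure_and_positive_definiteness(self):
        strong, weak = default_state_covariances()
        assert np.linalg.eigvalsh(strong).min() > 0
        assert np.linalg.eigvalsh(weak).min() > 0
        assert strong[0, 1] == 0.6      # within VIS
        assert strong[0, 19] == 0.3     # VIS vs DMN
        assert weak[0, 1] == pytest.approx(0.15)
        np.testing.assert_array_equal(np.diag(strong), 1.0)


class TestVoxelMixing:
    def test_maps_unit_norm_and_disjoint(self):
        spec = tiny_spec()
        maps = make_mixing_maps(spec)
        np.testing.assert_allclose(np.linalg.norm(maps, axis=1), 1.0)
        support = (maps > 0).astype(int).sum(axis=0)
        assert support.max() == 1       # no voxel shared by two blobs

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            make_mixing_maps(tiny_spec(spatial_grid=(8, 8, 4)))

    def test_noiseless_regression_recovers_timecourses(self, rng):
        spec = tiny_spec()
        maps = make_mixing_maps(spec)
        tc = rng.standard_normal((50, spec.n_components))
        img = gen_voxel_images(tc, maps, noise_sd=0.0, spec=spec)
        data = np.asarray(img.dataobj).reshape(-1, 50).T
        rec = np.linalg.lstsq(maps.T, data.T, rcond=None)[0].T
        for c in range(spec.n_components):
            assert abs(np.corrcoef(tc[:, c], rec[:, c])[0, 1]) > 0.999

    def test_single_component_voxels_proportional(self, rng):
        spec = tiny_spec()
        maps = make_mixing_maps(spec)[:1]
        tc = rng.standard_normal((30, 1))
        img = gen_voxel_images(tc, maps, noise_sd=0.0, spec=spec)
        data = np.asarray(img.dataobj).reshape(-1, 30).T
        v = np.flatnonzero(maps[0] > 0)[0]
        assert abs(np.corrcoef(tc[:, 0], data[:, v])[0, 1]) > 0.999999

    def test_header_records_tr(self, rng):
        spec = tiny_spec(tr_seconds=2.0)
        img = gen_voxel_images(rng.standard_normal((10, 20)),
                               make_mixing_maps(spec), 0.0, spec)
        assert img.header.get_zooms()[3] == pytest.approx(2.0)


class TestMotionTrace:
    def test_quiet_trace_is_zero(self):
        trace = gen_motion_trace(100, drift_sd=0.0, spike_prob=0.0, seed=0)
        assert np.all(trace == 0)
        assert np.all(framewise_displacement(trace) == 0)

    def test_spike_produces_fd_of_spike_size(self):
        trace = gen_motion_trace(200, drift_sd=0.0, spike_prob=0.05,
                                 spike_mm=2.0, seed=1)
        fd = framewise_displacement(trace)
        spikes = np.flatnonzero(fd)
        assert len(spikes) > 0
        np.testing.assert_allclose(fd[spikes], 2.0)

    def test_seed_reproducibility(self):
        a = gen_motion_trace(100, seed=7)
        b = gen_motion_trace(100, seed=7)
        np.testing.assert_array_equal(a, b)


class TestCohortBundle:
    def test_file_counts_for_tiny_cohort(self, tmp_path):
        man = gen_cohort(tiny_spec(seed=1), tmp_path)
        assert len(man["images"]) == 4
        assert len(man["motion"]) == 4
        assert Path(man["template"]).is_file()
        assert Path(man["sheet"]).is_file()
        assert Path(man["truth"]).is_file()

    def test_same_seed_gives_identical_truth(self, tmp_path):
        m1 = gen_cohort(tiny_spec(seed=2), tmp_path / "a", write_images=False)
        m2 = gen_cohort(tiny_spec(seed=2), tmp_path / "b", write_images=False)
        assert Path(m1["truth"]).read_bytes() == Path(m2["truth"]).read_bytes()

    def test_sheet_schema_and_groups(self, tmp_path):
        import pandas as pd
        man = gen_cohort(tiny_spec(seed=3), tmp_path, write_images=False)
        sheet = pd.read_csv(man["sheet"], sep="\t")
        assert list(sheet.columns) == ["subject_id", "group", "age_months",
                                       "sex", "duration_months"]
        assert (sheet["group"] == "patient").sum() == 2
        assert sheet.loc[sheet.group == "control", "duration_months"].isna().all()

    def test_template_labels_cover_all_networks(self, tmp_path):
        man = gen_cohort(tiny_spec(seed=4), tmp_path)
        labels = np.asarray(nib.load(man["template"]).dataobj)
        assert set(np.unique(labels)) == set(range(8))

    def test_higher_state2_persistence_raises_state2_occupancy(self, tmp_path):
        # group-level dwell asymmetry must show in the generated truth
        spec = CohortSpec(
            n_group_a=12, n_group_b=12, seed=5,
            stay_prob={"patient": (0.9, 0.97), "control": (0.95, 0.9)})
        man = gen_cohort(spec, tmp_path, write_images=False)
        truth = json.load(open(man["truth"]))
        frac2 = {"patient": [], "control": []}
        for sid, grp in zip(truth["subject_ids"], truth["groups"]):
            frac2[grp].append(truth["true_metrics"][sid]["frac_s2"])
        assert np.mean(frac2["patient"]) > np.mean(frac2["control"])


class TestMajorityVoteLabels:
    def test_pure_sequence_labels(self):
        states = np.concatenate([np.ones(60, int), np.full(60, 2, int)])
        wl = majority_vote_window_labels(states, width=30)
        assert len(wl) == 90
        assert np.all(wl[:45] == 1) and np.all(wl[46:] == 2)

    def test_tie_breaks_toward_state_one(self):
        states = np.concatenate([np.ones(15, int), np.full(16, 2, int)])
        wl = majority_vote_window_labels(states, width=30)
        assert wl[0] == 1
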