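"""Synthetic data generator: voxels, trials, HRF, time series, extraction."""

import numpy as np
import pandas as pd
import pytest

from depthiem import iem
from depthiem.geometry import make_grid
from depthiem.simulate import (
    HrfParams,
    SimConfig,
    calibrate_noise,
    extract_trial_estimates,
    hrf_double_gamma,
    make_voxels,
    simulate_experiment,
    simulate_timeseries,
    simulate_trial_responses,
)


class TestMakeVoxels:
    def test_reproducible_from_seed(self):
        a = make_voxels(50, seed=7)
        b = make_voxels(50, seed=7)
        assert np.array_equal(a.weights_x, b.weights_x)
        assert np.array_equal(a.weights_z, b.weights_z)
        assert a.n_voxels == 50

    def test_halfnormal_weights_nonnegative(self):
        v = make_voxels(200, weight_distribution="halfnorm", seed=1)
        assert np.all(v.weights_x >= 0) and np.all(v.weights_z >= 0)

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError, match="distribution"):
            make_voxels(5, weight_distribution="cauchy")

    def test_single_axis_tuning_zeroes_other_block(self):
        v = make_voxels(10, axis="z", seed=0)
        assert np.all(v.weights_x == 0) and np.any(v.weights_z != 0)


class TestTrialResponses:
    def test_zero_noise_equals_weighted_channel_activations(self, grid):
        vox = make_voxels(8, axis="z", noise_sd=0.0, seed=3)
        seq = [(r, c) for r in range(6) for c in range(6)]
        tm = simulate_trial_responses(vox, grid, seq, seed=0)
        for t, (r, c) in enumerate(seq):
            loc = grid.location(r, c)
            expected = vox.weights_z @ iem.channel_activations(
                loc.z_scene, vox.centers, vox.size).ravel()
            assert np.allclose(tm.responses[t], expected)

    def test_null_trials_are_pure_noise(self, grid):
        vox = make_voxels(5, noise_sd=0.0, seed=3)
        tm = simulate_trial_responses(vox, grid, [(0, 0), None], seed=0)
        assert np.all(tm.responses[1] == 0)
        assert tm.is_null[1] and not tm.is_null[0]

    def test_noise_mean_and_variance_match_spec(self, grid):
        # law of large numbers: mean -> W.X, variance -> noise_sd^2
        vox = make_voxels(3, axis="z", noise_sd=0.7, seed=5)
        seq = [(2, 3)] * 10_000
        tm = simulate_trial_responses(vox, grid, seq, seed=11)
        truth = vox.mean_response(grid.location(2, 3).x_scene,
                                  grid.location(2, 3).z_scene)[0]
        se = 0.7 / np.sqrt(10_000)
        assert np.all(np.abs(tm.responses.mean(axis=0) - truth) < 3 * se)
        assert np.allclose(tm.responses.var(axis=0), 0.49, rtol=0.1)

    def test_position_outside_grid_rejected(self, grid):
        vox = make_voxels(2, seed=0)
        with pytest.raises(KeyError):
            simulate_trial_responses(vox, grid, [(7, 0)], seed=0)

    def test_calibrate_noise_scales_peak(self, grid):
        vox = calibrate_noise(make_voxels(20, seed=2), grid, scale=0.5)
        xs = np.array([l.x_scene for l in grid.locations])
        zs = np.array([l.z_scene for l in grid.locations])
        peaks = np.abs(vox.mean_response(xs, zs)).max(axis=0)
        assert np.allclose(vox.noise_sd, 0.5 * peaks)


class TestExperiment:
    def test_structure_matches_design(self, small_experiment):
        exp = small_experiment
        assert len(exp.subjects) == 2
        for subj in exp.subjects:
            tm = subj.trials
            assert len(tm.runs) == 6
            for run in tm.runs:
                sel = tm.select(tm.run == run)
                assert sel.n_trials == 45
                assert int(sel.is_null.sum()) == 9
                assert int((~sel.is_null).sum()) == 36

    def test_even_runs_mirrored_by_default(self, small_experiment):
        for subj in small_experiment.subjects:
            tm = subj.trials
            for run in tm.runs:
                flag = tm.mirrored[tm.run == run]
                assert np.all(flag == (run % 2 == 0))

    def test_each_position_once_per_run(self, small_experiment):
        tm = small_experiment.subjects[0].trials.stimulus_trials()
        for run in tm.runs:
            sel = tm.select(tm.run == run)
            cells = {(r, c) for r, c in zip(sel.row, sel.col)}
            assert len(cells) == 36

    def test_default_config_has_nine_subjects(self):
        assert SimConfig().n_subjects == 9

    def test_seed_changes_noise_not_labels(self):
        cfg = SimConfig(n_subjects=1, n_runs=2, n_voxels=4, noise_scale=1.0)
        a = simulate_experiment(cfg, seed=1).subjects[0].trials
        b = simulate_experiment(cfg, seed=2).subjects[0].trials
        assert np.array_equal(a.row, b.row) and np.array_equal(a.col, b.col)
        assert not np.allclose(a.responses, b.responses)

    def test_fully_reproducible(self):
        cfg = SimConfig(n_subjects=1, n_runs=2, n_voxels=4)
        a = simulate_experiment(cfg, seed=9).subjects[0].trials
        b = simulate_experiment(cfg, seed=9).subjects[0].trials
        assert np.array_equal(a.responses, b.responses)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="cross-validation"):
            SimConfig(n_runs=1)


class TestHrf:
    def test_peaks_at_five_seconds(self):
        t = np.arange(0, 30, 0.01)
        h = hrf_double_gamma(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.05)

    def test_zero_at_onset(self):
        assert hrf_double_gamma(0.0) == 0.0

    def test_undershoot_is_negative(self):
        t = np.arange(10, 25, 0.1)
        assert hrf_double_gamma(t).min() < 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HrfParams(peak_s=-1.0)


class TestTimeseries:
    def test_run_length_is_150_volumes(self, grid):
        vox = make_voxels(3, seed=0)
        seq = [(r, c) for r in range(6) for c in range(6)] + [None] * 9
        ts = simulate_timeseries(vox, grid, seq, seed=0)
        assert ts.n_volumes == 150
        assert len(ts.events) == 45

    def test_isolated_trial_peaks_2_to_3_volumes_after_onset(self, grid):
        vox = make_voxels(1, axis="z", seed=4)
        ts = simulate_timeseries(vox, grid, [(5, 0)], duration_s=60.0,
                                 iti_range=(2.0, 2.0), seed=0)
        onset_vol = int(ts.events.loc[0, "onset_s"] // 2)
        peak_vol = int(np.argmax(ts.data[:, 0]))
        assert 2 <= peak_vol - onset_vol <= 4

    def test_reproducible(self, grid):
        vox = make_voxels(2, seed=0)
        a = simulate_timeseries(vox, grid, [(0, 0), None], noise_sd=0.5, seed=5)
        b = simulate_timeseries(vox, grid, [(0, 0), None], noise_sd=0.5, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_overfull_run_rejected(self, grid):
        vox = make_voxels(1, seed=0)
        seq = [(0, 0)] * 50
        with pytest.raises(ValueError, match="too short"):
            simulate_timeseries(vox, grid, seq, duration_s=100.0, seed=0)


class TestExtraction:
    def test_zscoring_and_positive_estimates(self, grid):
        vox = make_voxels(4, axis="z", seed=8)
        seq = [(5, 0), (5, 1), (5, 2), (5, 3)]
        ts = simulate_timeseries(vox, grid, seq, duration_s=120.0,
                                 noise_sd=0.0, seed=0)
        tm = extract_trial_estimates(ts, grid)
        driven = vox.mean_response(grid.location(5, 0).x_scene,
                                   grid.location(5, 0).z_scene)[0] > 1e-6
        assert np.all(tm.responses[:, driven] > 0)

    def test_constant_voxel_rejected(self, grid):
        vox = make_voxels(1, seed=0)
        ts = simulate_timeseries(vox, grid, [None, None, None],
                                 duration_s=60.0, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="constant"):
            extract_trial_estimates(ts, grid)

    def test_pipeline_equivalence_with_direct_responses(self, grid):
        # time-series route correlates with matrix-mode responses at low noise
        vox = make_voxels(12, axis="z", seed=21)
        seq = [(r, c) for r in range(6) for c in range(6)] + [None] * 9
        rng = np.random.default_rng(0)
        rng.shuffle(seq)
        ts = simulate_timeseries(vox, grid, seq, noise_sd=0.01, seed=2)
        tm_ts = extract_trial_estimates(ts, grid).stimulus_trials()
        tm_direct = simulate_trial_responses(vox, grid, seq, seed=3).stimulus_trials()
        for v in range(vox.n_voxels):
            if tm_direct.responses[:, v].std() < 1e-9:
                continue
            r = np.corrcoef(tm_ts.responses[:, v], tm_direct.responses[:, v])[0, 1]
            assert r > 0.9
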