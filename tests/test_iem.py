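"""Encoding model: basis, design matrix, weight estimation, inversion, CV."""

import numpy as np
import pytest

from depthiem import iem
from depthiem.iem import (
    ModelError,
    PixelGrid,
    average_by_position,
    basis_eval,
    build_basis,
    channel_activations,
    crossval_reconstruct,
    design_matrix,
    estimate_weights,
    invert_model,
    reconstruct,
    stimulus_profile,
)
from depthiem.simulate import SimConfig, make_voxels, simulate_experiment
from depthiem.trials import TrialMatrix


class TestBasisEval:
    def test_unit_peak_at_center(self):
        assert basis_eval(0.0, 1.8) == 1.0

    def test_half_size_value_is_half_to_the_seventh(self):
        assert basis_eval(0.9, 1.8) == pytest.approx(0.5 ** 7)

    def test_zero_outside_support(self):
        assert basis_eval(1.2 * 1.8, 1.8) == 0.0
        assert basis_eval(-2.5, 1.8) == 0.0

    @pytest.mark.parametrize("size", [1.2, 1.8, 2.4, 5.0])
    def test_bounded_and_symmetric(self, size):
        r = np.linspace(-6, 6, 301)
        v = basis_eval(r, size)
        assert np.all((v >= 0) & (v <= 1))
        assert np.allclose(v, v[::-1])

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            basis_eval(0.5, 0.0)


class TestBuildBasis:
    @pytest.mark.parametrize("size", [1.2, 1.8, 2.4])
    def test_six_rows_peaking_at_centers(self, pixel_grid, size):
        b = build_basis(pixel_grid, size=size)
        assert b.F.shape == (6, pixel_grid.n_pixels)
        for k, c in enumerate(b.centers):
            peak_px = pixel_grid.coords[np.argmax(b.F[k])]
            assert peak_px == pytest.approx(c, abs=pixel_grid.spacing)
            assert b.F[k].max() == pytest.approx(1.0, abs=1e-12)

    def test_support_width_matches_size(self, pixel_grid):
        b = build_basis(pixel_grid, size=1.8)
        row = b.F[2]  # center -0.3: support fully inside the domain
        nonzero = pixel_grid.coords[row > 0]
        assert nonzero.min() > -0.3 - 1.8 and nonzero.max() < -0.3 + 1.8

    def test_center_count_mismatch_rejected(self, pixel_grid):
        with pytest.raises(ValueError, match="centers"):
            build_basis(pixel_grid, centers=(-1.5, 0.0, 1.5), n_channels=6)

    def test_unsorted_centers_rejected(self, pixel_grid):
        with pytest.raises(ValueError):
            build_basis(pixel_grid, centers=(0.0, -0.5, 1.0, 1.2, 1.4, 1.6))


class TestStimulusProfile:
    def test_delta_is_one_hot_with_unit_mass(self, pixel_grid):
        p = stimulus_profile(-0.3, pixel_grid, "delta")
        assert p.sum() == 1.0
        assert np.count_nonzero(p) == 1
        assert pixel_grid.coords[np.argmax(p)] == pytest.approx(-0.3)

    def test_boxcar_covers_extent_with_unit_mass(self, pixel_grid):
        extent = 0.65  # 13 pixel spacings: count formula is exact on-lattice
        p = stimulus_profile(0.0, pixel_grid, "boxcar", extent=extent)
        expected_n = round(2 * extent / pixel_grid.spacing) + 1
        assert np.count_nonzero(p) == expected_n
        assert p.sum() == pytest.approx(1.0)

    def test_out_of_domain_rejected(self, pixel_grid):
        with pytest.raises(ValueError, match="outside"):
            stimulus_profile(3.0, pixel_grid, "delta")


class TestDesignMatrix:
    def test_one_hot_column_selects_basis_column(self, basis):
        S = np.zeros((basis.pixel_grid.n_pixels, 1))
        S[40, 0] = 1.0
        X = design_matrix(basis.F, S)
        assert np.allclose(X[:, 0], basis.F[:, 40])

    def test_linearity(self, basis, rng):
        p = basis.pixel_grid.n_pixels
        S1, S2 = rng.random((p, 4)), rng.random((p, 4))
        lhs = design_matrix(basis.F, 2.0 * S1 + 0.5 * S2)
        rhs = 2.0 * design_matrix(basis.F, S1) + 0.5 * design_matrix(basis.F, S2)
        assert np.allclose(lhs, rhs)

    def test_dimension_mismatch_rejected(self, basis):
        with pytest.raises(ModelError):
            design_matrix(basis.F, np.zeros((10, 3)))


class TestEstimateWeights:
    def test_identity_design_returns_responses(self, rng):
        B = rng.normal(size=(4, 6))
        W = estimate_weights(B, np.eye(6))
        assert np.allclose(W, B)

    def test_noiseless_consistency(self, rng):
        W = rng.normal(size=(10, 6))
        X = rng.random((6, 40))
        assert np.allclose(estimate_weights(W @ X, X), W, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        # independent per-voxel solve of X' w = b via lstsq
        X = rng.random((3, 20))
        B = rng.normal(size=(5, 20))
        W = estimate_weights(B, X)
        for v in range(5):
            w_oracle, *_ = np.linalg.lstsq(X.T, B[v], rcond=None)
            assert np.allclose(W[v], w_oracle, atol=1e-10)

    def test_rank_deficient_design_names_channels(self, rng):
        X = rng.random((4, 30))
        X[2] = 0.0  # unstimulated channel
        with pytest.raises(ModelError, match=r"\[2\]"):
            estimate_weights(rng.normal(size=(5, 30)), X)

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ModelError, match="trials"):
            estimate_weights(rng.normal(size=(5, 4)), rng.random((6, 4)))


class TestInvertModel:
    def test_left_inverse_recovers_channel_responses(self, rng):
        W = rng.normal(size=(12, 6))
        X2 = rng.random((6, 9))
        assert np.allclose(invert_model(W, W @ X2), X2, atol=1e-10)

    def test_orthonormal_weights_reduce_to_transpose(self):
        W, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(8, 4)))
        B2 = np.random.default_rng(1).normal(size=(8, 5))
        assert np.allclose(invert_model(W, B2), W.T @ B2, atol=1e-12)

    def test_matches_pinv_oracle(self, rng):
        W = rng.normal(size=(4, 2))
        B2 = rng.normal(size=(4, 7))
        assert np.allclose(invert_model(W, B2), np.linalg.pinv(W) @ B2,
                           atol=1e-10)

    def test_rank_deficient_weights_rejected(self, rng):
        W = rng.normal(size=(6, 3))
        W[:, 2] = W[:, 0]
        with pytest.raises(ModelError):
            invert_model(W, rng.normal(size=(6, 4)))


class TestReconstruct:
    def test_unit_channel_gives_scaled_basis_row(self, basis):
        X2 = np.zeros((6, 1))
        X2[3, 0] = 2.5
        curves = reconstruct(X2, basis.F)
        assert np.allclose(curves[0], 2.5 * basis.F[3])

    def test_zero_responses_give_flat_zero(self, basis):
        assert np.all(reconstruct(np.zeros((6, 2)), basis.F) == 0)

    def test_linear_in_channel_responses(self, basis, rng):
        A, B = rng.random((6, 3)), rng.random((6, 3))
        assert np.allclose(reconstruct(2 * A + B, basis.F),
                           2 * reconstruct(A, basis.F) + reconstruct(B, basis.F))


def _noiseless_dataset(basis, axis="z", n_runs=2, seed=0):
    cfg = SimConfig(n_subjects=1, n_runs=n_runs, n_voxels=20, noise_scale=0.0,
                    tuning_axis=axis)
    return simulate_experiment(cfg, seed=seed).subjects[0].trials


class TestCrossvalReconstruct:
    def test_noiseless_roundtrip_peaks_at_true_position(self, basis):
        tm = _noiseless_dataset(basis, axis="z")
        recon = crossval_reconstruct(tm, basis, axis="z")
        px = basis.pixel_grid.coords
        for k in range(recon.curves.shape[0]):
            peak = px[np.argmax(recon.curves[k])]
            assert abs(peak - recon.trials.z[k]) <= basis.pixel_grid.spacing

    def test_noiseless_channel_inversion_is_exact(self, basis):
        tm = _noiseless_dataset(basis, axis="z")
        recon = crossval_reconstruct(tm, basis, axis="z")
        S = np.column_stack([stimulus_profile(z, basis.pixel_grid)
                             for z in recon.trials.z])
        X_true = design_matrix(basis.F, S)
        assert np.max(np.abs(recon.channel_responses - X_true)) < 1e-8

    def test_row_count_matches_non_null_trials(self, basis, small_experiment):
        tm = small_experiment.subjects[0].trials
        recon = crossval_reconstruct(tm, basis, axis="z")
        assert recon.curves.shape[0] == int((~tm.is_null).sum())

    def test_two_runs_train_on_each_other(self, basis):
        # duplicated runs, zero noise: CV equals train-on-all reconstruction
        tm = _noiseless_dataset(basis, axis="z", n_runs=2)
        recon = crossval_reconstruct(tm, basis, axis="z")
        stim = tm.stimulus_trials()
        S = np.column_stack([stimulus_profile(z, basis.pixel_grid)
                             for z in stim.z])
        X = design_matrix(basis.F, S)
        W = estimate_weights(stim.responses.T, X)
        full = reconstruct(invert_model(W, stim.responses.T), basis.F)
        assert np.allclose(recon.curves, full, atol=1e-8)

    def test_linearity_in_test_responses(self, basis, small_experiment, rng):
        # with fixed training weights, reconstruction is linear in B2
        tm = small_experiment.subjects[0].trials.stimulus_trials()
        train = tm.select(tm.run != 1)
        S = np.column_stack([stimulus_profile(z, basis.pixel_grid)
                             for z in train.z])
        W = estimate_weights(train.responses.T, design_matrix(basis.F, S))
        B, Bp = rng.normal(size=(2, tm.n_voxels, 7))
        lhs = reconstruct(invert_model(W, 2.0 * B + 0.5 * Bp), basis.F)
        rhs = (2.0 * reconstruct(invert_model(W, B), basis.F)
               + 0.5 * reconstruct(invert_model(W, Bp), basis.F))
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_single_run_rejected(self, basis, small_experiment):
        tm = small_experiment.subjects[0].trials
        one = tm.select(tm.run == 1)
        with pytest.raises(ModelError, match="2 runs"):
            crossval_reconstruct(one, basis, axis="z")


class TestMirrorEquivariance:
    def test_mirrored_world_gives_reflected_reconstructions(self, basis):
        # mirror stimulus x AND voxel tuning -> pixel-reflected curves
        cfg = SimConfig(n_subjects=1, n_runs=2, n_voxels=15, noise_scale=0.0,
                        tuning_axis="x")
        tm = simulate_experiment(cfg, seed=5).subjects[0].trials
        recon = crossval_reconstruct(tm, basis, axis="x")

        vox = simulate_experiment(cfg, seed=5).subjects[0].voxels
        # reflected world: x -> -x, channel weights reversed (centers are
        # symmetric about 0, so reversing weights mirrors the tuning)
        fx = iem.channel_activations(-tm.x[~tm.is_null], vox.centers, vox.size)
        B_mir = (vox.weights_x[:, ::-1] @ fx).T
        stim = tm.stimulus_trials()
        tm_mir = TrialMatrix(responses=B_mir, run=stim.run, row=stim.row,
                             col=stim.col, x=-stim.x, z=stim.z,
                             is_null=stim.is_null, mirrored=stim.mirrored)
        recon_mir = crossval_reconstruct(tm_mir, basis, axis="x")
        assert np.allclose(recon_mir.curves, recon.curves[:, ::-1], atol=1e-8)


class TestAverageByPosition:
    def test_six_positions_per_axis(self, basis, small_experiment):
        tm = small_experiment.subjects[0].trials
        for axis in ("x", "z"):
            avg = average_by_position(crossval_reconstruct(tm, basis, axis=axis))
            assert avg.curves.shape[0] == 6
            assert len(avg.true_coords) == 6

    def test_z_axis_true_coords_are_row_depths(self, basis, small_experiment):
        tm = small_experiment.subjects[0].trials
        avg = average_by_position(crossval_reconstruct(tm, basis, axis="z"))
        assert np.allclose(avg.true_coords, [-1.5, -0.9, -0.3, 0.3, 0.9, 1.5])

    def test_equal_counts_mean(self, basis, small_experiment):
        tm = small_experiment.subjects[0].trials
        recon = crossval_reconstruct(tm, basis, axis="z")
        avg = average_by_position(recon)
        sel = recon.trials.row == 2
        assert np.allclose(avg.curves[2], recon.curves[sel].mean(axis=0))
        assert np.all(avg.counts == avg.counts[0])

    def test_double_reflection_is_identity(self, basis, small_experiment):
        tm = small_experiment.subjects[0].trials
        recon = crossval_reconstruct(tm, basis, axis="x")
        flipped_twice = recon.curves[:, ::-1][:, ::-1]
        assert np.array_equal(flipped_twice, recon.curves)

    def test_x_axis_groups_align_mirrored_runs(self, basis, small_experiment):
        # after unmirroring, each column group pools both run parities
        tm = small_experiment.subjects[0].trials
        avg = average_by_position(crossval_reconstruct(tm, basis, axis="x"))
        assert np.all(np.diff(avg.true_coords) > 0)
        # triangular stagger makes the column means only nearly antisymmetric
        assert np.allclose(avg.true_coords, -avg.true_coords[::-1], atol=0.02)
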