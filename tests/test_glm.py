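"""Raised-cosine basis, penalized likelihood, fitting, ridge selection, ACGs."""

import numpy as np
import pytest

from psfglm import (
    GroundTruthCell,
    build_basis,
    compute_acg,
    evaluate_psf,
    fit_glm,
    penalized_negloglik,
    predict_acg,
    select_ridge,
    simulate_spike_train,
)
from psfglm.glm import GLMFit, build_design, fit_place_only


def _random_instance(rng, n_bins=1500, basis=None):
    """Small synthetic instance for likelihood-level checks."""
    basis = basis or build_basis()
    r = (rng.random(n_bins) < 0.02).astype(float)
    p = rng.standard_normal(n_bins) * 0.5
    X = build_design(r, p, basis)
    return r, p, X, basis


class TestBasis:
    def test_shape_and_rank(self, basis):
        assert basis.matrix.shape == (700, 11)
        assert np.linalg.matrix_rank(basis.matrix) == 11

    def test_smooth_columns_nonnegative_single_peak(self, basis):
        for j in range(10):
            col = basis.matrix[:, j]
            assert np.all(col >= 0)
            peak = int(np.argmax(col))
            # unimodal: nondecreasing to the peak, nonincreasing after
            assert np.all(np.diff(col[: peak + 1]) >= -1e-12)
            assert np.all(np.diff(col[peak:]) <= 1e-12)
            assert np.trapezoid(col, basis.grid) > 0

    def test_impulse_is_first_bin_indicator(self, basis):
        imp = basis.matrix[:, 10]
        assert imp[0] == 1.0 and np.all(imp[1:] == 0.0)

    def test_smooth_columns_tile_support(self, basis):
        assert np.all(basis.matrix[1:, :10].sum(axis=1) > 0.5)

    def test_projection_recovers_unit_coefficients(self, basis):
        for j in (0, 4, 9):
            coefs, *_ = np.linalg.lstsq(basis.matrix, basis.matrix[:, j], rcond=None)
            expected = np.zeros(11)
            expected[j] = 1.0
            np.testing.assert_allclose(coefs, expected, atol=1e-8)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            build_basis(n_smooth=1)
        with pytest.raises(ValueError):
            build_basis(warp_offset=-0.01)
        with pytest.raises(ValueError):
            build_basis(duration=-1.0)


class TestPenalizedLikelihood:
    def test_penalty_monotone_in_xi(self, rng, basis):
        r, p, X, _ = _random_instance(rng, basis=basis)
        beta = rng.standard_normal(11) * 0.1
        nlls = [
            penalized_negloglik(0.0, 0.5, beta, r, p, basis, xi, design=X)[0]
            for xi in (0.1, 1.0, 10.0)
        ]
        assert nlls[0] < nlls[1] < nlls[2]

    def test_gradient_matches_finite_differences(self, rng, basis):
        for _ in range(5):
            r, p, X, _ = _random_instance(rng, basis=basis)
            theta = rng.standard_normal(13) * 0.2
            theta[0] = -4.0
            xi = 0.5
            nll, grad = penalized_negloglik(
                theta[0], theta[1], theta[2:], r, p, basis, xi, design=X
            )
            eps = 1e-6
            for k in range(13):
                tp, tm = theta.copy(), theta.copy()
                tp[k] += eps
                tm[k] -= eps
                fp = penalized_negloglik(tp[0], tp[1], tp[2:], r, p, basis, xi, design=X)[0]
                fm = penalized_negloglik(tm[0], tm[1], tm[2:], r, p, basis, xi, design=X)[0]
                fd = (fp - fm) / (2 * eps)
                assert abs(grad[k] - fd) / max(abs(fd), 1e-8) < 1e-5

    def test_homogeneous_closed_form_stationarity(self, rng, basis):
        # with beta = 0 and alpha1 = 0 the optimum is alpha0 = log(N / duration)
        r, p, X, _ = _random_instance(rng, n_bins=4000, basis=basis)
        alpha0 = np.log(r.sum() / (r.size * 1e-3))
        _, grad = penalized_negloglik(
            alpha0, 0.0, np.zeros(11), r, np.zeros_like(p), basis, 1.0
        )
        assert abs(grad[0]) < 1e-8


class TestFit:
    def test_same_optimum_from_multiple_inits(self, rng, basis):
        r, p, X, _ = _random_instance(rng, n_bins=20000, basis=basis)
        fits = []
        for k in range(3):
            init = np.zeros(13)
            init[0] = -4.0
            init += 0.3 * np.random.default_rng(k).standard_normal(13)
            fits.append(fit_glm(r, p, basis, xi=1.0, init=init, design=X))
        for f in fits[1:]:
            assert np.linalg.norm(f.theta - fits[0].theta) < 1e-4
            assert f.converged

    def test_ridge_limit_shrinks_history(self, basis, traj120):
        cell = GroundTruthCell(
            field_centers=[[0, 0]], field_widths=[10], field_gains=[0],
            psf_beta=np.zeros(11), alpha0=np.log(5.0), alpha1=0.0, profile="flat",
        )
        train = simulate_spike_train(traj120, cell, basis, seed=3)
        p = np.zeros(train.counts.size)
        small = fit_glm(train, p, basis, xi=0.01)
        large = fit_glm(train, p, basis, xi=1e6)
        assert np.linalg.norm(large.beta[:10]) < 1e-2 * np.linalg.norm(small.beta[:10])

    def test_empty_train_rejected(self, basis):
        with pytest.raises(ValueError):
            fit_glm(np.zeros(1000), np.zeros(1000), basis)

    def test_nonconvergence_is_flagged(self, rng, basis):
        r, p, X, _ = _random_instance(rng, basis=basis)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = fit_glm(r, p, basis, xi=1.0, max_iter=1, design=X)
        assert not fit.converged

    def test_place_only_matches_homogeneous_rate(self, basis, traj120):
        cell = GroundTruthCell(
            field_centers=[[0, 0]], field_widths=[10], field_gains=[0],
            psf_beta=np.zeros(11), alpha0=np.log(4.0), alpha1=0.0, profile="flat",
        )
        train = simulate_spike_train(traj120, cell, basis, seed=5)
        fit = fit_place_only(train, np.zeros(train.counts.size))
        assert fit.alpha0 == pytest.approx(np.log(train.mean_rate), abs=1e-6)
        assert fit.beta.size == 0


class TestRidgeSelection:
    def test_single_point_grid(self, basis, traj120):
        cell = GroundTruthCell(
            field_centers=[[0, 0]], field_widths=[10], field_gains=[0],
            psf_beta=np.zeros(11), alpha0=np.log(5.0), alpha1=0.0, profile="flat",
        )
        train = simulate_spike_train(traj120, cell, basis, seed=4)
        assert select_ridge(train, np.zeros(train.counts.size), basis, [3.14]) == 3.14

    def test_invalid_grid_rejected(self, basis):
        with pytest.raises(ValueError):
            select_ridge(np.ones(10), np.zeros(10), basis, [])
        with pytest.raises(ValueError):
            select_ridge(np.ones(10), np.zeros(10), basis, [-1.0, 1.0])


class TestPSFEvaluation:
    def test_zero_beta_gives_unit_gain(self, basis):
        fit = GLMFit(0.0, 0.0, np.zeros(11), 1.0, 0.0, 0.0, True, 1, 0.0)
        psf = evaluate_psf(fit, basis)
        assert np.all(psf.values == 0)
        assert np.all(psf.gain == 1.0)

    def test_unit_vector_reproduces_basis_column(self, basis):
        beta = np.zeros(11)
        beta[2] = 1.0
        fit = GLMFit(0.0, 0.0, beta, 1.0, 0.0, 0.0, True, 1, 0.0)
        psf = evaluate_psf(fit, basis)
        np.testing.assert_array_equal(psf.values, basis.matrix[:, 2])
        np.testing.assert_array_equal(psf.smooth_component, basis.matrix[:, 2])

    def test_gain_strictly_positive(self, rng, basis):
        fit = GLMFit(0.0, 0.0, rng.standard_normal(11), 1.0, 0.0, 0.0, True, 1, 0.0)
        assert np.all(evaluate_psf(fit, basis).gain > 0)


class TestACG:
    def test_poisson_acg_flat_within_bands(self, basis, traj900):
        cell = GroundTruthCell(
            field_centers=[[0, 0]], field_widths=[10], field_gains=[0],
            psf_beta=np.zeros(11), alpha0=np.log(5.0), alpha1=0.0, profile="flat",
        )
        train = simulate_spike_train(traj900, cell, basis, seed=6)
        acg = compute_acg(train)  # 10-ms boxcar
        lam = train.mean_rate
        expected = lam * lam * 900.0 * 1e-3  # pair count per 1-ms lag bin
        se = np.sqrt(expected / 10.0)  # boxcar averages 10 bins
        # skip the boxcar's zero-padded edges
        assert np.all(np.abs(acg.values[10:-10] - expected) < 4 * se)

    def test_regular_train_peaks_at_period_multiples(self):
        st_ = np.arange(0.0, 60.0, 0.1)
        acg = compute_acg(st_, smoothing_window=0.0)
        peaks = np.nonzero(acg.values > 0)[0]
        assert set(peaks) <= {99, 100, 199, 200, 299, 300, 399, 400, 499, 500, 599, 600}

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError):
            compute_acg(np.array([1.0]))

    def test_normalized_acg_has_unit_area(self):
        rng = np.random.default_rng(7)
        st_ = np.sort(rng.uniform(0, 300, 1500))
        acg = compute_acg(st_, normalize=True)
        assert np.trapezoid(acg.values, acg.lags) == pytest.approx(1.0, rel=0.05)


class TestPredictedACG:
    def test_history_free_fit_predicts_flat_acg(self, basis, traj120):
        fit = GLMFit(np.log(8.0), 0.0, np.zeros(11), 1.0, 0.0, 0.0, True, 1, 0.0)
        p = np.zeros(120000)
        acg = predict_acg(fit, traj120, basis, p, n_sim=10, seed=8)
        body = acg.values[20:]
        assert body.std() / body.mean() < 0.25

    def test_mc_band_shrinks_with_n_sim(self, basis, traj120):
        fit = GLMFit(np.log(8.0), 0.0, np.zeros(11), 1.0, 0.0, 0.0, True, 1, 0.0)
        p = np.zeros(120000)

        def spread(n_sim, seeds):
            curves = [
                predict_acg(fit, traj120, basis, p, n_sim=n_sim, seed=s).values
                for s in seeds
            ]
            return np.mean(np.var(curves, axis=0))

        v2 = spread(2, range(8))
        v8 = spread(8, range(8, 16))
        # variance of the mean scales as 1/n_sim (factor 4 here, loosely)
        assert v8 < v2 / 1.8
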