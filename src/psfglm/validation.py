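"""Simulation-based validation studies of the GLM pipeline.

Each function runs one self-contained study against synthetic ground truth
and returns the measured quantities: exactness of the likelihood gradient,
recovery of generating post-spike filters, closure of the predicted
autocorrelation, closed-form feature checks, coherence sanity, phenotype
clustering accuracy, regression calibration and ridge-selection behavior.
They are used by the test suite and by ``scripts/acceptance.py``; all
randomness is controlled by the ``seed`` argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import population as pop_mod
from .basis import RaisedCosineBasis, build_basis
from .features import (
    NormalizedPSF,
    PSFFeatures,
    burstiness,
    normalize_unit_power,
    theta_features,
)
from .glm import (
    build_design,
    compute_acg,
    evaluate_psf,
    fit_glm,
    fit_place_only,
    penalized_negloglik,
    predict_acg,
    select_ridge,
    DEFAULT_XI_GRID,
)
from .maps import RateMap, compute_coherence
from .synthetic import (
    ArenaSpec,
    GroundTruthCell,
    generate_population,
    make_ground_truth_psf,
    resample_position,
    simulate_spike_train,
    simulate_trajectory,
    _arena_field_peak,
)

__all__ = [
    "gradient_check",
    "psf_recovery_study",
    "acg_closure_study",
    "cosine_feature_checks",
    "coherence_checks",
    "clustering_study",
    "regression_study",
    "ridge_selection_study",
]


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# 1. analytic gradient vs central finite differences


def gradient_check(
    seed: int = 0, n_instances: int = 50, n_bins: int = 1200, eps: float = 1e-6
) -> dict:
    """Max relative error between analytic and finite-difference gradients.

    Random small instances: Bernoulli spike trains, Gaussian place
    covariates, random parameter points; every coordinate of the gradient is
    compared against a central difference.
    """
    basis = build_basis()
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        r = (rng.random(n_bins) < rng.uniform(0.005, 0.03)).astype(float)
        p = rng.standard_normal(n_bins) * rng.uniform(0.3, 1.0)
        X = build_design(r, p, basis)
        theta = rng.standard_normal(13) * 0.2
        theta[0] = rng.uniform(-5.0, -3.0)
        xi = float(rng.uniform(0.1, 5.0))
        _, grad = penalized_negloglik(
            theta[0], theta[1], theta[2:], r, p, basis, xi, design=X
        )
        fd = np.empty(13)
        for k in range(13):
            h = eps * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fp = penalized_negloglik(tp[0], tp[1], tp[2:], r, p, basis, xi, design=X)[0]
            fm = penalized_negloglik(tm[0], tm[1], tm[2:], r, p, basis, xi, design=X)[0]
            fd[k] = (fp - fm) / (2 * h)
        rel = float(np.linalg.norm(grad - fd) / np.linalg.norm(fd))
        worst = max(worst, rel)
    return {"max_rel_err": worst, "n_instances": n_instances}


# ---------------------------------------------------------------------------
# 2./3. PSF recovery and ACG closure on a synthetic cohort


@dataclass
class RecoveryStudy:
    correlations: list[float]
    sign_correct: list[bool]
    cells: list[GroundTruthCell]
    trains: list
    traj: object
    fits: list
    covariates: list[np.ndarray]
    basis: RaisedCosineBasis

    @property
    def median_correlation(self) -> float:
        return float(np.median(self.correlations))

    @property
    def sign_fraction(self) -> float:
        return float(np.mean(self.sign_correct))


def psf_recovery_study(
    seed: int = 0,
    n_cells: int = 20,
    duration: float = 900.0,
    xi: float = 1.0,
) -> RecoveryStudy:
    """Fit the GLM to a synthetic cohort and compare fitted vs true PSFs.

    For each cell the correlation between the true and fitted normalized
    smooth PSF is recorded, along with whether the sign of the immediate
    (0-30 ms) lobe of the smooth component was recovered.
    """
    arena = ArenaSpec()
    basis = build_basis()
    pop = generate_population(
        n_cells, seed=seed, arena=arena, duration=duration, basis=basis
    )
    traj = pop[0][2]
    _, xb, yb = resample_position(traj, basis.delta)

    corrs, signs, fits, covs, cells, trains = [], [], [], [], [], []
    for cell, train, _ in pop:
        p = cell.place_map(xb, yb) / _arena_field_peak(cell, arena)
        sd = p.std()
        p = (p - p.mean()) / sd if sd > 0 else np.zeros_like(p)
        fit = fit_glm(train, p, basis, xi=xi)
        true_s = basis.expand_smooth(cell.psf_beta)
        fit_s = evaluate_psf(fit, basis).smooth_component
        corrs.append(float(np.corrcoef(true_s, fit_s)[0, 1]))
        g30 = basis.grid[:31]
        signs.append(
            bool(
                np.sign(np.trapezoid(true_s[:31], g30))
                == np.sign(np.trapezoid(fit_s[:31], g30))
            )
        )
        fits.append(fit)
        covs.append(p)
        cells.append(cell)
        trains.append(train)
    return RecoveryStudy(
        correlations=corrs,
        sign_correct=signs,
        cells=cells,
        trains=trains,
        traj=traj,
        fits=fits,
        covariates=covs,
        basis=basis,
    )


def acg_closure_study(
    study: RecoveryStudy, n_sim: int = 6, seed: int = 0
) -> dict:
    """Does the fitted PSF improve prediction of the data ACG?

    For every cohort cell with a nonzero true PSF, the integrated squared
    error between the (area-normalized, 10-ms smoothed) data ACG and the
    model-predicted ACG is compared between the full GLM and the
    place-field-only (inhomogeneous Poisson) reference.
    """
    wins, ise_full, ise_place = [], [], []
    seeds = _sub_seeds(seed, 2 * len(study.fits))
    for k, (cell, train, fit, p) in enumerate(
        zip(study.cells, study.trains, study.fits, study.covariates)
    ):
        if not np.any(cell.psf_beta):
            continue
        data = compute_acg(train, normalize=True)
        full = predict_acg(
            fit, study.traj, study.basis, p, n_sim=n_sim, seed=seeds[2 * k]
        )
        place = fit_place_only(train, p)
        po = predict_acg(
            place, study.traj, study.basis, p, n_sim=n_sim, seed=seeds[2 * k + 1]
        )
        f = float(np.trapezoid((full.values - data.values) ** 2, data.lags))
        g = float(np.trapezoid((po.values - data.values) ** 2, data.lags))
        ise_full.append(f)
        ise_place.append(g)
        wins.append(f < g)
    return {
        "win_fraction": float(np.mean(wins)),
        "n_cells": len(wins),
        "ise_full": ise_full,
        "ise_place": ise_place,
    }


# ---------------------------------------------------------------------------
# 4. closed-form feature checks


def cosine_feature_checks(seed: int = 0, n_random: int = 20) -> dict:
    """Feature extraction against closed forms and a fine-grid quadrature.

    Checks the unit-power 9-Hz cosine (self-correlation, peak latency,
    trough window), the constant unit-power filter (burstiness closed form)
    and, on random smooth filters, agreement of the trapezoid integrals with
    a midpoint Riemann sum at 0.1-ms resolution.
    """
    basis = build_basis()
    g = basis.grid

    cos_psf = normalize_unit_power(np.cos(2 * np.pi * 9.0 * g), g)
    f = theta_features(cos_psf)
    win = (g >= 0.042) & (g <= 0.083)
    trough_time = float(g[win][np.argmin(cos_psf.values[win])])

    const = NormalizedPSF(
        values=np.full(g.size, 1.0 / np.sqrt(0.7)), grid=g, source_power=1.0
    )
    burst_const = burstiness(const)

    rng = np.random.default_rng(seed)
    step = (g[1] - g[0]) / 10.0
    fine = np.arange(g[0], g[-1], step) + step / 2.0
    worst = 0.0
    for _ in range(n_random):
        fn = normalize_unit_power(
            basis.expand_smooth(rng.standard_normal(10)), g
        )
        vals_fine = np.interp(fine, g, fn.values)
        feats = theta_features(fn)
        for (lo, hi), impl in (
            ((0.0, 0.030), feats.burstiness),
            ((0.083, 0.250), feats.theta_integral),
        ):
            m = (fine >= lo) & (fine <= hi)
            oracle = float(np.sum(vals_fine[m]) * step)
            worst = max(worst, abs(impl - oracle) / max(abs(oracle), 1e-9))
    return {
        "cosine_theta_correlation": f.theta_correlation,
        "cosine_theta_peak_time": f.theta_peak_time,
        "cosine_trough_time": trough_time,
        "burstiness_constant": burst_const,
        "burstiness_constant_expected": 0.03 / np.sqrt(0.7),
        "integral_max_rel_err": worst,
    }


# ---------------------------------------------------------------------------
# 5. spatial coherence sanity


def coherence_checks(seed: int = 0, n_shuffles: int = 50) -> dict:
    """Scale invariance, checkerboard hand-computation and shuffle null."""
    # 4x4 checkerboard vs explicit 16-pixel computation
    rate = (np.indices((4, 4)).sum(axis=0) % 2).astype(float)
    r_impl = compute_coherence(RateMap.from_array(rate), fisher_z=False)
    vals, nbrs = [], []
    for i in range(4):
        for j in range(4):
            acc = [
                rate[i + di, j + dj]
                for di in (-1, 0, 1)
                for dj in (-1, 0, 1)
                if (di, dj) != (0, 0) and 0 <= i + di < 4 and 0 <= j + dj < 4
            ]
            vals.append(rate[i, j])
            nbrs.append(float(np.mean(acc)))
    r_hand = float(np.corrcoef(vals, nbrs)[0, 1])

    rng = np.random.default_rng(seed)
    base = rng.random((10, 10))
    z0 = compute_coherence(RateMap.from_array(base))
    scale_diff = max(
        abs(compute_coherence(RateMap.from_array(c * base)) - z0)
        for c in (1e-3, 0.5, 7.0, 1e3)
    )
    shuffles = [
        compute_coherence(RateMap.from_array(rng.permutation(base.ravel()).reshape(10, 10)))
        for _ in range(n_shuffles)
    ]
    return {
        "checkerboard": r_impl,
        "checkerboard_hand": r_hand,
        "scale_invariance_max_diff": float(scale_diff),
        "shuffle_mean_abs": float(np.mean(np.abs(shuffles))),
        "shuffle_null_band": 3.0 / np.sqrt(100),
    }


# ---------------------------------------------------------------------------
# 6. clustering recovery


def clustering_study(seed: int = 0, n_cells: int = 100) -> dict:
    """k-means (k=2, correlation distance) vs ground-truth phenotype labels
    on an 80/20 bursty/refractory population."""
    basis = build_basis()
    pop = generate_population(n_cells, seed=seed, duration=30.0, basis=basis)
    curves = np.vstack(
        [
            normalize_unit_power(basis.expand_smooth(c.psf_beta), basis.grid).values
            for c, _, _ in pop
        ]
    )
    labels = np.array([c.profile for c, _, _ in pop])
    res = pop_mod.cluster_psfs(curves, seed=seed)
    return {
        "accuracy": float(np.mean(res.labels == labels)),
        "n_cells": n_cells,
        "within_correlation": res.within_correlation,
        "between_correlation": res.between_correlation,
    }


# ---------------------------------------------------------------------------
# 7. regression calibration


def regression_study(
    seed: int = 0, n_cells: int = 200, n_seeds: int = 20, signal_fraction: float = 0.6
) -> dict:
    """Spearman r^2 recovery when coherence is a linear function of theta
    features plus noise at a known signal fraction.

    The feature table comes from the generating filters of a bursty
    population (the phenotype whose theta features the regression targets);
    the synthetic coherence is built with signal variance ``signal_fraction``
    and the main-effects regression's predicted-vs-observed Spearman r^2 is
    averaged over ``n_seeds`` noise draws.  The noiseless case is reported
    alongside as the exactness check.
    """
    basis = build_basis()
    pop = generate_population(
        n_cells,
        seed=seed,
        duration=5.0,
        basis=basis,
        group_spec=[{"profile": "bursty", "fraction": 1.0}],
    )
    rows = [
        theta_features(
            normalize_unit_power(basis.expand_smooth(c.psf_beta), basis.grid)
        ).as_dict()
        for c, _, _ in pop
    ]
    F = pd.DataFrame(rows)[list(PSFFeatures.FEATURE_NAMES)]

    theta_cols = [
        "theta_peak", "theta_trough", "theta_depth",
        "theta_correlation", "theta_integral",
    ]
    w = np.array([1.0, -0.5, 0.8, 0.6, 1.2])
    G = F[theta_cols].to_numpy()
    G = (G - G.mean(axis=0)) / G.std(axis=0)
    signal = G @ w
    signal = (signal - signal.mean()) / signal.std()

    r2s = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for s in _sub_seeds(seed, n_seeds):
            rng = np.random.default_rng(s)
            y = np.sqrt(signal_fraction) * signal + np.sqrt(
                1 - signal_fraction
            ) * rng.standard_normal(n_cells)
            r2s.append(
                pop_mod.regress_coherence(F, y, interactions=False).spearman_r2
            )
        noiseless = pop_mod.regress_coherence(
            F, signal, interactions=False
        ).spearman_r2
    return {
        "spearman_r2_mean": float(np.mean(r2s)),
        "spearman_r2_sd": float(np.std(r2s)),
        "noiseless_spearman_r2": float(noiseless),
        "n_cells": n_cells,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 8. evidence-based ridge selection behavior


def ridge_selection_study(seed: int = 0, duration: float = 300.0) -> dict:
    """Ridge selection on history-free vs strongly history-structured data.

    On Poisson data (flat PSF) the evidence should push the penalty to the
    grid maximum; with a strong true PSF it should settle below it.
    """
    arena = ArenaSpec()
    basis = build_basis()
    s_traj, s_flat, s_struct = _sub_seeds(seed, 3)
    traj = simulate_trajectory(arena, duration, 15.0, seed=s_traj)
    _, xb, yb = resample_position(traj, basis.delta)

    flat = GroundTruthCell(
        field_centers=[[0.0, 0.0]], field_widths=[10.0], field_gains=[1.0],
        psf_beta=np.zeros(11), alpha0=np.log(4.0), alpha1=0.8, profile="flat",
    )
    structured = GroundTruthCell(
        field_centers=[[0.0, 0.0]], field_widths=[10.0], field_gains=[1.0],
        psf_beta=make_ground_truth_psf("bursty", basis),
        alpha0=np.log(2.5), alpha1=0.7, profile="bursty",
    )
    out = {}
    for name, cell, s in (("poisson", flat, s_flat), ("structured", structured, s_struct)):
        p = cell.place_map(xb, yb) / _arena_field_peak(cell, arena)
        p = (p - p.mean()) / p.std()
        train = simulate_spike_train(traj, cell, basis, seed=s, arena=arena)
        out[f"xi_{name}"] = float(select_ridge(train, p, basis, DEFAULT_XI_GRID))
    out["xi_grid_max"] = float(DEFAULT_XI_GRID.max())
    return out
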