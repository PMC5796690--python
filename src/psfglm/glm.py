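"""Point-process GLM separating place-driven rate from fine spike timing.

The model for a 1-ms binned spike train r(t) is

    lambda(t) = exp(alpha0 + alpha1 * p(x(t), y(t)) + sum_tau r(tau) f_beta(t - tau))

with p the (standardized) place-field covariate, and f_beta the post-spike
filter expanded on the raised-cosine basis.  Fitting maximizes the penalized
log-likelihood

    L = sum_t [ r(t) log(lambda(t) Delta) - lambda(t) Delta ] - xi ||beta||^2

by Newton's method with backtracking line search; only the 11 basis
coefficients are penalized, the place field and baseline being treated as
covariates.  The ridge strength xi is selected on a grid by maximizing the
Laplace-approximated model evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .basis import RaisedCosineBasis
from .synthetic import (
    BinnedSpikeTrain,
    TrajectorySample,
    simulate_from_intensity,
)

__all__ = [
    "GLMFit",
    "PSF",
    "ACG",
    "build_design",
    "penalized_negloglik",
    "fit_glm",
    "select_ridge",
    "evaluate_psf",
    "compute_acg",
    "predict_acg",
]

DEFAULT_XI_GRID = np.logspace(-2, 4, 10)


@dataclass
class GLMFit:
    """Fitted GLM parameters and diagnostics."""

    alpha0: float
    alpha1: float
    beta: np.ndarray
    xi: float
    loglik: float  # unpenalized log-likelihood at the optimum
    penalized_loglik: float
    converged: bool
    n_iter: int
    gradient_norm: float

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([[self.alpha0, self.alpha1], self.beta])


@dataclass(frozen=True)
class PSF:
    """Post-spike filter on the 1-ms lag grid.

    ``values`` includes the impulse term; ``smooth_component`` is the
    raised-cosine expansion of the first 10 coefficients only.  ``exp`` of
    either curve is the multiplicative post-spike gain.
    """

    values: np.ndarray
    smooth_component: np.ndarray
    beta: np.ndarray
    grid: np.ndarray

    @property
    def gain(self) -> np.ndarray:
        return np.exp(self.values)


@dataclass(frozen=True)
class ACG:
    """One-sided spike-train autocorrelogram."""

    lags: np.ndarray  # seconds, bin centers
    values: np.ndarray
    smoothing_window: float  # seconds (0 = unsmoothed)
    normalized: bool = False


def _as_counts(spikes: BinnedSpikeTrain | np.ndarray) -> tuple[np.ndarray, float]:
    if isinstance(spikes, BinnedSpikeTrain):
        return np.asarray(spikes.counts, dtype=float), spikes.delta
    return np.asarray(spikes, dtype=float), 1e-3


def build_design(
    spikes: BinnedSpikeTrain | np.ndarray,
    place_covariate: np.ndarray,
    basis: RaisedCosineBasis,
) -> np.ndarray:
    """Design matrix [1, p(t), H(t, 1..11)] on the 1-ms lattice.

    ``H[t, i]`` is the basis column i evaluated at the lags to all previous
    spikes, i.e. the spike train convolved causally with each basis function
    (the first basis bin weights the bin immediately after a spike).
    """
    r, _ = _as_counts(spikes)
    T = r.size
    p = np.asarray(place_covariate, dtype=float)
    if p.size != T:
        raise ValueError(
            f"place covariate length {p.size} != number of bins {T}"
        )
    if not np.all(np.isfinite(p)):
        raise ValueError("place covariate must be finite")
    X = np.zeros((T, 2 + basis.n_functions))
    X[:, 0] = 1.0
    X[:, 1] = p
    B = basis.matrix
    L = B.shape[0]
    for t0 in np.nonzero(r)[0]:
        hi = min(t0 + 1 + L, T)
        if hi > t0 + 1:
            X[t0 + 1 : hi, 2:] += B[: hi - (t0 + 1)]
    return X


def _negloglik_grad(
    theta: np.ndarray,
    r: np.ndarray,
    X: np.ndarray,
    xi: float,
    delta: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Penalized negative log-likelihood, gradient and lambda*Delta."""
    eta = X @ theta
    if not np.all(np.isfinite(eta)):
        bad = int(np.nonzero(~np.isfinite(eta))[0][0])
        raise FloatingPointError(f"non-finite log-intensity at bin {bad}")
    lam_dt = np.exp(eta) * delta
    if not np.all(np.isfinite(lam_dt)):
        bad = int(np.nonzero(~np.isfinite(lam_dt))[0][0])
        raise FloatingPointError(f"non-finite intensity at bin {bad}")
    spk = r > 0
    ll = float(r[spk] @ np.log(lam_dt[spk]) - lam_dt.sum())
    pen = np.zeros_like(theta)
    pen[2:] = 2.0 * xi * theta[2:]
    nll = -ll + xi * float(theta[2:] @ theta[2:])
    grad = -(X.T @ (r - lam_dt)) + pen
    return nll, grad, lam_dt


def penalized_negloglik(
    alpha0: float,
    alpha1: float,
    beta: np.ndarray,
    spikes: BinnedSpikeTrain | np.ndarray,
    place_covariate: np.ndarray,
    basis: RaisedCosineBasis,
    xi: float,
    design: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Negative penalized log-likelihood -L and its analytic gradient.

    The gradient is with respect to the stacked parameter vector
    (alpha0, alpha1, beta_1..beta_11); only beta is penalized.
    """
    r, delta = _as_counts(spikes)
    X = design if design is not None else build_design(spikes, place_covariate, basis)
    theta = np.concatenate([[alpha0, alpha1], np.asarray(beta, dtype=float)])
    nll, grad, _ = _negloglik_grad(theta, r, X, xi, delta)
    return nll, grad


def fit_glm(
    spikes: BinnedSpikeTrain | np.ndarray,
    place_covariate: np.ndarray,
    basis: RaisedCosineBasis | None,
    xi: float = 1.0,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    design: np.ndarray | None = None,
) -> GLMFit:
    """Penalized maximum-likelihood fit by Newton's method.

    The penalized log-likelihood is strictly concave in
    (alpha0, alpha1, beta) for xi > 0, so Newton with backtracking line
    search converges to the unique optimum from any start; convergence is
    declared when the gradient norm falls below ``tol`` (scaled by the
    number of spikes). Deterministic given ``init``.
    """
    r, delta = _as_counts(spikes)
    n_spikes = float(r.sum())
    if n_spikes == 0:
        raise ValueError("cannot fit GLM to an empty spike train")
    X = design if design is not None else build_design(spikes, place_covariate, basis)
    n_params = X.shape[1]

    if init is None:
        theta = np.zeros(n_params)
        theta[0] = np.log(n_spikes / (r.size * delta))
    else:
        theta = np.asarray(init, dtype=float).copy()
        if theta.shape != (n_params,):
            raise ValueError(f"init must have shape ({n_params},)")

    pen_diag = np.zeros(n_params)
    pen_diag[2:] = 2.0 * xi
    grad_scale = max(n_spikes, 1.0)

    nll, grad, lam_dt = _negloglik_grad(theta, r, X, xi, delta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H = (X.T * lam_dt) @ X + np.diag(pen_diag)
        try:
            step = linalg.cho_solve(linalg.cho_factor(H), grad)
        except linalg.LinAlgError:
            step = grad / (np.abs(np.diag(H)).max() + 1.0)
        # backtracking line search on the penalized NLL
        stepsize = 1.0
        for _ in range(50):
            trial = theta - stepsize * step
            try:
                nll_t, grad_t, lam_t = _negloglik_grad(trial, r, X, xi, delta)
            except FloatingPointError:
                stepsize *= 0.5
                continue
            if nll_t <= nll - 1e-4 * stepsize * float(grad @ step):
                theta, nll, grad, lam_dt = trial, nll_t, grad_t, lam_t
                break
            stepsize *= 0.5
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol * grad_scale:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GLM fit did not converge in {max_iter} iterations "
            f"(gradient norm {gnorm:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )

    beta = theta[2:]
    pen_ll = -nll
    return GLMFit(
        alpha0=float(theta[0]),
        alpha1=float(theta[1]),
        beta=beta.copy(),
        xi=float(xi),
        loglik=pen_ll + xi * float(beta @ beta),
        penalized_loglik=pen_ll,
        converged=converged,
        n_iter=it,
        gradient_norm=gnorm,
    )


def fit_place_only(
    spikes: BinnedSpikeTrain | np.ndarray,
    place_covariate: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> GLMFit:
    """Rate-code-only reference model: lambda(t) = exp(alpha0 + alpha1 p(t)).

    An inhomogeneous Poisson model with no spike-history term, used as the
    baseline against which the post-spike filter's contribution to the
    autocorrelation structure is judged.  Returned with ``beta`` empty.
    """
    p = np.asarray(place_covariate, dtype=float)
    X = np.column_stack([np.ones(p.size), p])
    return fit_glm(
        spikes, p, basis=None, xi=0.0, tol=tol, max_iter=max_iter, design=X
    )


def log_evidence(
    fit: GLMFit,
    spikes: BinnedSpikeTrain | np.ndarray,
    place_covariate: np.ndarray,
    basis: RaisedCosineBasis,
    design: np.ndarray | None = None,
) -> float:
    """Laplace-approximated log marginal likelihood at a fitted optimum.

    log Z ~= L_pen(theta_hat) + (k/2) log(2 xi) - (1/2) log det H_beta,
    where k is the number of penalized coefficients and H_beta is the
    beta-block of the penalized-NLL Hessian at the mode (constants dropped;
    only grid comparisons are meaningful).
    """
    r, delta = _as_counts(spikes)
    X = design if design is not None else build_design(spikes, place_covariate, basis)
    _, _, lam_dt = _negloglik_grad(fit.theta, r, X, fit.xi, delta)
    k = basis.n_functions
    Xb = X[:, 2:]
    Hb = (Xb.T * lam_dt) @ Xb + 2.0 * fit.xi * np.eye(k)
    sign, logdet = np.linalg.slogdet(Hb)
    if sign <= 0:
        return -np.inf
    return fit.penalized_loglik + 0.5 * k * np.log(2.0 * fit.xi) - 0.5 * logdet


def select_ridge(
    spikes: BinnedSpikeTrain | np.ndarray,
    place_covariate: np.ndarray,
    basis: RaisedCosineBasis,
    xi_grid: np.ndarray = DEFAULT_XI_GRID,
    return_fits: bool = False,
):
    """Evidence-maximizing ridge penalty from a grid.

    Fits the GLM at each grid point and returns the xi maximizing the
    Laplace-approximated evidence; ties break toward the larger penalty.
    """
    xi_grid = np.asarray(xi_grid, dtype=float)
    if xi_grid.size == 0 or np.any(xi_grid <= 0):
        raise ValueError("xi_grid must be non-empty and positive")
    if xi_grid.size == 1:
        if return_fits:
            f = fit_glm(spikes, place_covariate, basis, xi=float(xi_grid[0]))
            return float(xi_grid[0]), {float(xi_grid[0]): f}
        return float(xi_grid[0])

    X = build_design(spikes, place_covariate, basis)
    best_xi, best_ev = None, -np.inf
    fits: dict[float, GLMFit] = {}
    init = None
    for xi in np.sort(xi_grid):
        fit = fit_glm(spikes, place_covariate, basis, xi=float(xi), init=init, design=X)
        init = fit.theta  # warm start along the path
        ev = log_evidence(fit, spikes, place_covariate, basis, design=X)
        fits[float(xi)] = fit
        if np.isfinite(ev) and ev >= best_ev:  # >= : ties toward larger xi
            best_xi, best_ev = float(xi), ev
    if best_xi is None:
        raise ValueError("evidence non-finite on the whole xi grid")
    return (best_xi, fits) if return_fits else best_xi


def evaluate_psf(fit: GLMFit, basis: RaisedCosineBasis) -> PSF:
    """Expand fitted coefficients into the PSF and its smooth component."""
    return PSF(
        values=basis.expand(fit.beta),
        smooth_component=basis.expand_smooth(fit.beta),
        beta=fit.beta.copy(),
        grid=basis.grid.copy(),
    )


def compute_acg(
    spike_times: np.ndarray | BinnedSpikeTrain,
    max_lag: float = 0.65,
    bin_width: float = 1e-3,
    smoothing_window: float = 10e-3,
    gaussian: bool = False,
    normalize: bool = False,
) -> ACG:
    """One-sided autocorrelogram of a spike train.

    Histogram of positive spike-pair lags up to ``max_lag`` at ``bin_width``
    resolution, smoothed with a boxcar of ``smoothing_window`` (default
    10 ms).  ``gaussian=True`` switches to a Gaussian smoothing kernel whose
    window is interpreted as the FWHM-like width (sigma = window / 2), and
    ``normalize=True`` scales the curve to unit area, for cross-cell shape
    comparison.
    """
    if isinstance(spike_times, BinnedSpikeTrain):
        spike_times = spike_times.spike_times
    st = np.sort(np.asarray(spike_times, dtype=float))
    if st.size < 2:
        raise ValueError("ACG needs at least 2 spikes")

    n_bins = int(round(max_lag / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    # all positive spike-pair lags within max_lag, in one histogram pass
    hi = np.searchsorted(st, st + max_lag, side="right")
    chunks = [
        st[i + 1 : hi[i]] - st[i] for i in range(st.size - 1) if hi[i] > i + 1
    ]
    all_lags = np.concatenate(chunks) if chunks else np.empty(0)
    values = np.histogram(all_lags, bins=edges)[0].astype(float)
    if smoothing_window and smoothing_window > 0:
        w = max(int(round(smoothing_window / bin_width)), 1)
        if gaussian:
            from scipy.ndimage import gaussian_filter1d

            values = gaussian_filter1d(values, sigma=w / 2.0, mode="nearest")
        else:
            kernel = np.ones(w) / w
            values = np.convolve(values, kernel, mode="same")
    if normalize:
        area = values.sum() * bin_width
        if area > 0:
            values = values / area
    lags = (edges[:-1] + edges[1:]) / 2.0
    return ACG(
        lags=lags,
        values=values,
        smoothing_window=smoothing_window if smoothing_window else 0.0,
        normalized=normalize,
    )


def predict_acg(
    fit: GLMFit,
    traj: TrajectorySample,
    basis: RaisedCosineBasis,
    place_covariate: np.ndarray,
    n_sim: int = 8,
    seed: int = 0,
    max_lag: float = 0.65,
    smoothing_window: float = 10e-3,
    normalize: bool = True,
) -> ACG:
    """Model-predicted ACG: average over trains simulated from the fit.

    Simulates ``n_sim`` spike trains from the fitted conditional intensity
    on the given trajectory/covariate and averages their autocorrelograms.
    With ``normalize=True`` each simulated ACG is area-normalized before
    averaging so the prediction is comparable to a normalized data ACG.
    """
    delta = basis.delta
    base = fit.alpha0 + fit.alpha1 * np.asarray(place_covariate, dtype=float)
    psf_values = (
        basis.expand(fit.beta) if fit.beta.size else np.zeros(basis.n_bins)
    )
    ss = np.random.SeedSequence(seed).spawn(n_sim)
    acc = None
    n_ok = 0
    for k in range(n_sim):
        train = simulate_from_intensity(
            base, psf_values, delta, seed=int(ss[k].generate_state(1)[0] % 2**31)
        )
        if train.n_spikes < 2:
            continue
        acg = compute_acg(
            train,
            max_lag=max_lag,
            smoothing_window=smoothing_window,
            normalize=normalize,
        )
        acc = acg.values if acc is None else acc + acg.values
        n_ok += 1
    if acc is None:
        raise ValueError("no simulated train produced >= 2 spikes")
    lags = (np.arange(int(round(max_lag / delta))) + 0.5) * delta
    return ACG(
        lags=lags,
        values=acc / n_ok,
        smoothing_window=smoothing_window,
        normalized=normalize,
    )
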