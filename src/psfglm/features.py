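"""Fine-spike-timing features of the post-spike filter.

All features are computed on the unit-power normalized *smooth component* of
the PSF, so they describe the shape of the post-spike modulation independent
of its overall magnitude:

- burstiness: integral over the immediate 0-30 ms post-spike window;
- theta peak / peak time: maximum over one theta cycle post spike
  (83-167 ms) and its latency;
- theta trough: minimum over the half-cycle window (42-83 ms);
- theta depth: peak minus trough;
- theta correlation C_theta: maximum Pearson correlation with a cosine
  A*cos(2*pi*omega*t), omega scanned over 6-12 Hz (the positive amplitude A
  does not affect a Pearson correlation, so only omega is searched);
- theta integral: integral over 83-250 ms (one theta cycle of area);
- rate-normalized power P(f) = r * integral of f^2, with r the mean rate,
  computed on the raw (unnormalized) smooth component.

The PSF is represented by its values on the 1-ms lag lattice and treated as
piecewise linear between lattice points; all integrals are therefore exact
integrals of that representation (trapezoid rule on the native grid, with
inclusive window endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import PSF

__all__ = [
    "NormalizedPSF",
    "PSFFeatures",
    "rate_normalized_power",
    "normalize_unit_power",
    "burstiness",
    "theta_features",
    "extract_features",
    "THETA_BAND",
]

THETA_BAND = (6.0, 12.0)  # Hz
BURST_WINDOW = (0.0, 0.030)  # s
THETA_PEAK_WINDOW = (0.083, 0.167)  # s, one theta cycle post spike
THETA_TROUGH_WINDOW = (0.042, 0.083)  # s
THETA_INTEGRAL_WINDOW = (0.083, 0.250)  # s


@dataclass(frozen=True)
class NormalizedPSF:
    """Unit-power PSF curve: integral of values**2 over the support is 1."""

    values: np.ndarray
    grid: np.ndarray
    source_power: float  # raw power of the input curve


@dataclass(frozen=True)
class PSFFeatures:
    """The seven fine-spike-timing descriptors of one cell."""

    burstiness: float
    theta_peak: float
    theta_peak_time: float
    theta_trough: float
    theta_depth: float
    theta_correlation: float
    theta_integral: float
    theta_frequency: float  # argmax frequency of the cosine correlation (Hz)
    rate_normalized_power: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "burstiness": self.burstiness,
            "theta_peak": self.theta_peak,
            "theta_peak_time": self.theta_peak_time,
            "theta_trough": self.theta_trough,
            "theta_depth": self.theta_depth,
            "theta_correlation": self.theta_correlation,
            "theta_integral": self.theta_integral,
            "theta_frequency": self.theta_frequency,
            "rate_normalized_power": (
                np.nan
                if self.rate_normalized_power is None
                else self.rate_normalized_power
            ),
        }

    FEATURE_NAMES = (
        "burstiness",
        "theta_peak",
        "theta_peak_time",
        "theta_trough",
        "theta_depth",
        "theta_correlation",
        "theta_integral",
    )


def _window_slice(grid: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Boolean mask of grid points in [lo, hi], endpoints inclusive."""
    eps = 1e-12
    return (grid >= lo - eps) & (grid <= hi + eps)


def _trapz_window(
    values: np.ndarray, grid: np.ndarray, lo: float, hi: float
) -> float:
    m = _window_slice(grid, lo, hi)
    return float(np.trapezoid(values[m], grid[m]))


def raw_power(values: np.ndarray, grid: np.ndarray) -> float:
    """Integral of f(s)^2 over the PSF support (trapezoid)."""
    values = np.asarray(values, dtype=float)
    return float(np.trapezoid(values**2, grid))


def rate_normalized_power(
    psf: PSF | np.ndarray, mean_rate: float, grid: np.ndarray | None = None
) -> float:
    """P(f) = r * integral f(s)^2 ds over the PSF support.

    Computed on the smooth component; normalizes away the inverse relation
    between raw PSF power and firing rate (low-rate cells carry more
    modulation per spike).
    """
    if mean_rate < 0:
        raise ValueError("mean_rate must be non-negative")
    if isinstance(psf, PSF):
        values, grid = psf.smooth_component, psf.grid
    else:
        values = np.asarray(psf, dtype=float)
        if grid is None:
            grid = np.arange(values.size) * 1e-3
    return mean_rate * raw_power(values, grid)


def normalize_unit_power(
    psf: PSF | np.ndarray, grid: np.ndarray | None = None
) -> NormalizedPSF:
    """Rescale a PSF curve to unit power: integral of f_norm^2 = 1.

    Operates on the smooth component when given a full PSF.  Scale-invariant
    (f and c*f for c > 0 normalize identically) and idempotent.

    Raises
    ------
    ValueError
        For an identically-zero input, whose normalization is undefined.
    """
    if isinstance(psf, PSF):
        values, grid = psf.smooth_component, psf.grid
    else:
        values = np.asarray(psf, dtype=float)
        if grid is None:
            grid = np.arange(values.size) * 1e-3
    power = raw_power(values, grid)
    if power <= 0:
        raise ValueError("zero-power PSF: unit-power normalization undefined")
    return NormalizedPSF(
        values=values / np.sqrt(power), grid=np.asarray(grid, float), source_power=power
    )


def burstiness(f_norm: NormalizedPSF) -> float:
    """Integral of the normalized PSF over the immediate 0-30 ms window."""
    return _trapz_window(f_norm.values, f_norm.grid, *BURST_WINDOW)


def theta_features(
    f_norm: NormalizedPSF, freq_step: float = 0.05
) -> PSFFeatures:
    """Theta-band descriptors of a unit-power PSF.

    The peak/trough are window extrema on the 1-ms grid; C_theta scans
    cosine frequencies over 6-12 Hz in ``freq_step`` increments across the
    full PSF support.  A constant input has no theta structure: C_theta is
    0 by convention and depth is 0.
    """
    v, g = f_norm.values, f_norm.grid

    pk = _window_slice(g, *THETA_PEAK_WINDOW)
    i_pk = int(np.argmax(v[pk]))
    theta_peak = float(v[pk][i_pk])
    theta_peak_time = float(g[pk][i_pk])

    tr = _window_slice(g, *THETA_TROUGH_WINDOW)
    theta_trough = float(np.min(v[tr]))
    theta_depth = theta_peak - theta_trough

    theta_int = _trapz_window(v, g, *THETA_INTEGRAL_WINDOW)

    freqs = np.arange(THETA_BAND[0], THETA_BAND[1] + freq_step / 2, freq_step)
    vc = v - v.mean()
    denom_v = np.sqrt(float(vc @ vc))
    best_c, best_f = 0.0, float(freqs[0])
    if denom_v > 0:
        best_c = -np.inf
        for f in freqs:
            w = np.cos(2 * np.pi * f * g)
            wc = w - w.mean()
            c = float(vc @ wc) / (denom_v * np.sqrt(float(wc @ wc)))
            if c > best_c:
                best_c, best_f = c, float(f)
    return PSFFeatures(
        burstiness=burstiness(f_norm),
        theta_peak=theta_peak,
        theta_peak_time=theta_peak_time,
        theta_trough=theta_trough,
        theta_depth=theta_depth,
        theta_correlation=best_c,
        theta_integral=theta_int,
        theta_frequency=best_f,
    )


def extract_features(psf: PSF, mean_rate: float | None = None) -> PSFFeatures:
    """Full feature set from a fitted PSF (smooth component only)."""
    f_norm = normalize_unit_power(psf)
    feats = theta_features(f_norm)
    p = None if mean_rate is None else rate_normalized_power(psf, mean_rate)
    return PSFFeatures(
        burstiness=feats.burstiness,
        theta_peak=feats.theta_peak,
        theta_peak_time=feats.theta_peak_time,
        theta_trough=feats.theta_trough,
        theta_depth=feats.theta_depth,
        theta_correlation=feats.theta_correlation,
        theta_integral=feats.theta_integral,
        theta_frequency=feats.theta_frequency,
        rate_normalized_power=p,
    )
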