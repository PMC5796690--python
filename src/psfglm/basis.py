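"""Raised-cosine temporal basis for post-spike filters.

The post-spike filter (PSF) f(s) describes how the log firing intensity of a
neuron is modulated as a function of the time ``s`` since each of its previous
spikes.  It is parametrized on a bank of smooth "raised cosine bump" functions
whose centers are equi-spaced in log-warped time, so that early post-spike
dynamics (refractoriness, bursting) are resolved at millisecond precision
while slower theta-timescale structure is covered by broad bumps, plus a
single 1-ms impulse column that absorbs the absolute refractory period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RaisedCosineBasis", "build_basis"]


@dataclass(frozen=True)
class RaisedCosineBasis:
    """Bank of log-time raised cosine bumps plus a first-bin impulse.

    Attributes
    ----------
    matrix : ndarray, shape (n_bins, n_smooth + 1)
        Basis functions evaluated on the 1-ms lattice. Columns
        ``0..n_smooth-1`` are the smooth bumps; the last column is the
        impulse (indicator of the first bin).
    grid : ndarray, shape (n_bins,)
        Lag times in seconds, ``grid[k] = k * delta``.
    """

    matrix: np.ndarray
    grid: np.ndarray
    n_smooth: int
    delta: float
    duration: float
    warp_offset: float

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_functions(self) -> int:
        return self.matrix.shape[1]

    @property
    def smooth(self) -> np.ndarray:
        """The smooth (raised cosine) columns only."""
        return self.matrix[:, : self.n_smooth]

    @property
    def impulse(self) -> np.ndarray:
        return self.matrix[:, self.n_smooth]

    def expand(self, beta: np.ndarray) -> np.ndarray:
        """Evaluate f_beta(s) = sum_i beta_i b_i(s) on the lag grid."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.n_functions,):
            raise ValueError(
                f"expected {self.n_functions} coefficients, got {beta.shape}"
            )
        return self.matrix @ beta

    def expand_smooth(self, beta: np.ndarray) -> np.ndarray:
        """Evaluate the smooth component only (impulse term excluded)."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape == (self.n_functions,):
            beta = beta[: self.n_smooth]
        if beta.shape != (self.n_smooth,):
            raise ValueError(
                f"expected {self.n_smooth} smooth coefficients, got {beta.shape}"
            )
        return self.smooth @ beta

    def evaluate_smooth_at(self, s: np.ndarray) -> np.ndarray:
        """Evaluate the smooth columns at arbitrary lag times (seconds)."""
        return _smooth_columns(
            np.asarray(s, dtype=float),
            self.n_smooth,
            self.warp_offset,
            self.delta,
            self.duration,
        )


def _warp(s: np.ndarray, psi: float) -> np.ndarray:
    return np.log(s + psi)


def _smooth_columns(
    s: np.ndarray, n_smooth: int, psi: float, delta: float, duration: float
) -> np.ndarray:
    u = _warp(s, psi)
    c_first = _warp(np.asarray(delta), psi)
    c_last = _warp(np.asarray(duration), psi)
    centers = np.linspace(c_first, c_last, n_smooth)
    spacing = (c_last - c_first) / (n_smooth - 1)
    arg = (u[:, None] - centers[None, :]) * np.pi / (2.0 * spacing)
    cols = 0.5 * (1.0 + np.cos(np.clip(arg, -np.pi, np.pi)))
    cols[np.abs(arg) >= np.pi] = 0.0
    return cols


def build_basis(
    n_smooth: int = 10,
    duration: float = 0.7,
    delta: float = 1e-3,
    warp_offset: float = 0.015,
) -> RaisedCosineBasis:
    """Construct the PSF basis on the 1-ms lattice.

    Parameters
    ----------
    n_smooth : int
        Number of raised cosine bumps (>= 2).
    duration : float
        PSF support in seconds; the last bump peaks at this lag.
    delta : float
        Bin width in seconds (the spike-train clock).
    warp_offset : float
        Offset ``psi`` of the log-time warp ``u = log(s + psi)`` in seconds.
        Smaller values concentrate more bumps at short lags.

    Returns
    -------
    RaisedCosineBasis
        With ``matrix`` of shape ``(round(duration/delta), n_smooth + 1)``
        evaluated at lags ``s_k = k * delta`` for ``k = 0..n_bins-1``.
    """
    if n_smooth < 2:
        raise ValueError("n_smooth must be >= 2")
    if duration <= 0 or delta <= 0:
        raise ValueError("duration and delta must be positive")
    if warp_offset <= 0:
        raise ValueError("warp_offset must be positive (log-time warp)")

    n_bins = int(round(duration / delta))
    grid = np.arange(n_bins) * delta
    smooth = _smooth_columns(grid, n_smooth, warp_offset, delta, duration)

    # tiling check: the bumps must jointly cover the support without gaps
    interior = slice(1, n_bins)
    coverage = smooth[interior].sum(axis=1)
    if np.any(coverage <= 1e-12):
        raise ValueError(
            "warp parameters leave gaps in the basis tiling of (0, duration]"
        )

    impulse = np.zeros((n_bins, 1))
    impulse[0, 0] = 1.0
    matrix = np.hstack([smooth, impulse])
    if np.linalg.matrix_rank(matrix) < matrix.shape[1]:
        raise ValueError("basis matrix is rank deficient")

    return RaisedCosineBasis(
        matrix=matrix,
        grid=grid,
        n_smooth=n_smooth,
        delta=delta,
        duration=duration,
        warp_offset=warp_offset,
    )
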