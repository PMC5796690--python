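"""Place-field estimation and spatial firing statistics.

Rate maps p(x, y) are computed by smoothing spatially binned spike counts
and occupancy (time spent per pixel) with a shared 2D Gaussian kernel and
taking their ratio; the kernel bandwidth is chosen by 5-fold cross-validation
of the held-out inhomogeneous-Poisson log-likelihood.  Spatial coherence --
the correlation between each pixel's rate and the mean rate of its 8 visited
neighbors, optionally Fisher z-transformed -- quantifies the fidelity of the
spatial rate code and defines the classical place-cell criterion
(coherence >= 0.3).  Sessions are speed-filtered (>= 5 cm/s) before mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic import ArenaSpec, TrajectorySample

__all__ = [
    "OccupancyMap",
    "RateMap",
    "FiringStats",
    "speed_filter",
    "compute_occupancy",
    "compute_rate_map",
    "select_bandwidth_cv",
    "compute_coherence",
    "classify_place_cell",
    "peak_rate",
    "firing_stats",
]

DEFAULT_BIN_SIZE = 2.5  # cm -> 30 x 30 grid over a 75-cm arena
DEFAULT_SPEED_THRESHOLD = 5.0  # cm/s
DEFAULT_OCCUPANCY_FLOOR = 0.1  # s of smoothed occupancy below which a pixel is masked
RATE_FLOOR = 1e-9  # Hz floor inside CV log-likelihoods


@dataclass(frozen=True)
class OccupancyMap:
    """Seconds spent per pixel (speed-filtered)."""

    grid: np.ndarray
    bin_size: float
    visited_mask: np.ndarray
    edges_x: np.ndarray
    edges_y: np.ndarray

    @property
    def total_time(self) -> float:
        return float(self.grid.sum())


@dataclass(frozen=True)
class RateMap:
    """Smoothed firing-rate map p(x, y) in Hz.

    ``rate`` is NaN on masked pixels (unvisited or below the smoothed
    occupancy floor). ``cv_loglik`` is populated when the bandwidth was
    selected by cross-validation.
    """

    rate: np.ndarray
    bandwidth: float
    bin_size: float
    visited_mask: np.ndarray
    occupancy: OccupancyMap
    smoothed_occupancy: np.ndarray
    cv_loglik: float | None = None

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.rate)

    @classmethod
    def from_array(cls, rate: np.ndarray, bin_size: float = 2.5) -> "RateMap":
        """Wrap a raw rate grid (NaN = unvisited) as a RateMap.

        Occupancy is set to a uniform 1 s per visited pixel; intended for
        analyzing externally-computed or synthetic maps.
        """
        rate = np.asarray(rate, dtype=float)
        visited = np.isfinite(rate)
        n = rate.shape[0]
        edges = np.arange(n + 1) * bin_size - n * bin_size / 2.0
        occ = OccupancyMap(
            grid=visited.astype(float),
            bin_size=bin_size,
            visited_mask=visited,
            edges_x=edges,
            edges_y=edges,
        )
        return cls(
            rate=rate,
            bandwidth=0.0,
            bin_size=bin_size,
            visited_mask=visited,
            occupancy=occ,
            smoothed_occupancy=occ.grid,
        )

    @property
    def peak_rate(self) -> float:
        return peak_rate(self)

    def covariate_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Rate-map value at positions (cm); nearest valid pixel for gaps."""
        ix = np.clip(
            np.digitize(x, _edges(self)[0]) - 1, 0, self.rate.shape[0] - 1
        )
        iy = np.clip(
            np.digitize(y, _edges(self)[1]) - 1, 0, self.rate.shape[1] - 1
        )
        vals = self.rate[ix, iy]
        if np.any(~np.isfinite(vals)):
            fill = np.nanmean(self.rate)
            vals = np.where(np.isfinite(vals), vals, fill)
        return vals


def _edges(rm: RateMap) -> tuple[np.ndarray, np.ndarray]:
    return rm.occupancy.edges_x, rm.occupancy.edges_y


@dataclass(frozen=True)
class FiringStats:
    """Session-level firing statistics of one cell."""

    mean_rate: float
    instantaneous_freq: float | None
    coverage: float
    n_spikes: int


def speed_filter(
    traj: TrajectorySample, threshold: float = DEFAULT_SPEED_THRESHOLD
) -> np.ndarray:
    """Boolean mask of position samples moving at >= threshold cm/s."""
    return traj.speed >= threshold


def spike_mask_from_position_mask(
    spike_times: np.ndarray, traj: TrajectorySample, position_mask: np.ndarray
) -> np.ndarray:
    """Spikes inherit the mask of the position sample containing them."""
    idx = np.clip(np.searchsorted(traj.t, spike_times, side="right") - 1, 0, len(traj.t) - 1)
    return position_mask[idx]


def compute_occupancy(
    traj: TrajectorySample,
    arena: ArenaSpec | None = None,
    bin_size: float = DEFAULT_BIN_SIZE,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    position_mask: np.ndarray | None = None,
) -> OccupancyMap:
    """Speed-filtered time-per-pixel histogram over the arena square."""
    arena = arena or ArenaSpec()
    if position_mask is None:
        position_mask = speed_filter(traj, speed_threshold)
    n_bins = int(np.ceil(arena.diameter / bin_size))
    half = n_bins * bin_size / 2.0
    edges = np.linspace(-half, half, n_bins + 1)
    dt = traj.dt
    grid, *_ = np.histogram2d(
        traj.x[position_mask], traj.y[position_mask], bins=[edges, edges]
    )
    grid = grid * dt
    return OccupancyMap(
        grid=grid,
        bin_size=bin_size,
        visited_mask=grid > 0,
        edges_x=edges,
        edges_y=edges,
    )


def compute_rate_map(
    spike_times: np.ndarray,
    traj: TrajectorySample,
    bin_size: float = DEFAULT_BIN_SIZE,
    bandwidth: float = 5.0,
    arena: ArenaSpec | None = None,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    occupancy_floor: float = DEFAULT_OCCUPANCY_FLOOR,
) -> RateMap:
    """Gaussian-smoothed spike count / occupancy ratio map.

    Both the binned spike counts and the occupancy map are smoothed with the
    same 2D Gaussian kernel (``bandwidth`` in cm) before division; pixels
    whose smoothed occupancy falls below ``occupancy_floor`` seconds are
    masked (NaN).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    arena = arena or ArenaSpec(bin_size=bin_size)
    pos_mask = speed_filter(traj, speed_threshold)
    occ = compute_occupancy(traj, arena, bin_size, position_mask=pos_mask)
    if occ.total_time <= 0:
        raise ValueError("zero occupancy after speed filtering")

    spike_times = np.asarray(spike_times, dtype=float)
    smask = spike_mask_from_position_mask(spike_times, traj, pos_mask)
    sx = np.interp(spike_times[smask], traj.t, traj.x)
    sy = np.interp(spike_times[smask], traj.t, traj.y)
    spk, *_ = np.histogram2d(sx, sy, bins=[occ.edges_x, occ.edges_y])

    sigma = bandwidth / bin_size
    sm_spk = ndimage.gaussian_filter(spk, sigma=sigma, mode="constant")
    sm_occ = ndimage.gaussian_filter(occ.grid, sigma=sigma, mode="constant")

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = sm_spk / sm_occ
    masked = (sm_occ < occupancy_floor) | ~np.isfinite(rate)
    rate = np.where(masked, np.nan, rate)
    return RateMap(
        rate=rate,
        bandwidth=bandwidth,
        bin_size=bin_size,
        visited_mask=occ.visited_mask,
        occupancy=occ,
        smoothed_occupancy=sm_occ,
    )


def _poisson_map_loglik(
    spk: np.ndarray, occ: np.ndarray, rate: np.ndarray
) -> float:
    """Inhomogeneous-Poisson log-likelihood of binned spikes given a map."""
    lam = np.maximum(np.nan_to_num(rate, nan=0.0), RATE_FLOOR)
    use = occ > 0
    return float(np.sum(spk[use] * np.log(lam[use]) - lam[use] * occ[use]))


def select_bandwidth_cv(
    spike_times: np.ndarray,
    traj: TrajectorySample,
    candidate_bandwidths: np.ndarray,
    folds: int = 5,
    bin_size: float = DEFAULT_BIN_SIZE,
    arena: ArenaSpec | None = None,
    speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
    occupancy_floor: float = DEFAULT_OCCUPANCY_FLOOR,
) -> float:
    """Pick the smoothing bandwidth by k-fold cross-validated likelihood.

    The session is split into ``folds`` contiguous time blocks; for each
    candidate bandwidth a rate map fitted on the training blocks is scored
    by the inhomogeneous-Poisson log-likelihood of the held-out block's
    spike counts and occupancy.  Ties break toward the larger bandwidth.
    A training fold with no spikes scores the held-out data under the
    spike-free (floor-rate) map rather than erroring.
    """
    candidates = np.asarray(candidate_bandwidths, dtype=float)
    if candidates.size == 0:
        raise ValueError("need at least one candidate bandwidth")
    if candidates.size == 1:
        return float(candidates[0])
    if folds < 2:
        raise ValueError("folds must be >= 2")

    arena = arena or ArenaSpec(bin_size=bin_size)
    spike_times = np.asarray(spike_times, dtype=float)
    pos_mask = speed_filter(traj, speed_threshold)
    smask = spike_mask_from_position_mask(spike_times, traj, pos_mask)
    spike_times = spike_times[smask]

    t0, t1 = traj.t[0], traj.t[-1]
    bounds = np.linspace(t0, t1, folds + 1)
    n_bins = int(np.ceil(arena.diameter / bin_size))
    half = n_bins * bin_size / 2.0
    edges = np.linspace(-half, half, n_bins + 1)
    dt = traj.dt

    # per-fold raw spike-count and occupancy grids
    fold_spk, fold_occ = [], []
    for k in range(folds):
        in_t = (traj.t >= bounds[k]) & (traj.t < bounds[k + 1]) & pos_mask
        in_s = (spike_times >= bounds[k]) & (spike_times < bounds[k + 1])
        occ, *_ = np.histogram2d(traj.x[in_t], traj.y[in_t], bins=[edges, edges])
        sx = np.interp(spike_times[in_s], traj.t, traj.x)
        sy = np.interp(spike_times[in_s], traj.t, traj.y)
        spk, *_ = np.histogram2d(sx, sy, bins=[edges, edges])
        fold_spk.append(spk)
        fold_occ.append(occ * dt)

    total_spk = np.sum(fold_spk, axis=0)
    total_occ = np.sum(fold_occ, axis=0)

    best_bw, best_score = None, -np.inf
    for bw in candidates:
        sigma = bw / bin_size
        score = 0.0
        for k in range(folds):
            tr_spk = ndimage.gaussian_filter(
                total_spk - fold_spk[k], sigma=sigma, mode="constant"
            )
            tr_occ = ndimage.gaussian_filter(
                total_occ - fold_occ[k], sigma=sigma, mode="constant"
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                rate = np.where(tr_occ > occupancy_floor, tr_spk / tr_occ, np.nan)
            score += _poisson_map_loglik(fold_spk[k], fold_occ[k], rate)
        if score >= best_score:  # ties toward larger bandwidth (ascending scan)
            best_bw, best_score = float(bw), score
    assert best_bw is not None
    return best_bw


def compute_coherence(rate_map: RateMap, fisher_z: bool = True) -> float:
    """Spatial coherence of a rate map.

    Pearson correlation between each valid pixel's rate and the mean rate of
    its valid 8-neighbors (edge pixels use the neighbors they have), Fisher
    z-transformed by default (``arctanh r``); set ``fisher_z=False`` for the
    raw correlation.

    Raises
    ------
    ValueError
        If fewer than 9 valid pixels are available or the map (or its
        neighbor means) has zero variance, where coherence is undefined.
    """
    rate = rate_map.rate
    valid = np.isfinite(rate)
    if valid.sum() < 9:
        raise ValueError("coherence needs at least 9 valid pixels")

    filled = np.where(valid, rate, 0.0)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nbr_sum = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    use = valid & (nbr_cnt > 0)
    x = rate[use]
    y = nbr_sum[use] / nbr_cnt[use]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("coherence undefined: constant rate map")
    r = float(np.corrcoef(x, y)[0, 1])
    if not fisher_z:
        return r
    return float(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)))


def classify_place_cell(coherence: float, threshold: float = 0.3) -> bool:
    """Classical place-cell criterion: spatial coherence >= threshold."""
    if not np.isfinite(coherence):
        raise ValueError("coherence undefined")
    return bool(coherence >= threshold)


def peak_rate(rate_map: RateMap) -> float:
    """Mean rate of the highest-firing pixel and its valid 8-neighbors."""
    rate = rate_map.rate
    valid = np.isfinite(rate)
    if not valid.any():
        raise ValueError("no valid pixels in rate map")
    flat_idx = np.nanargmax(rate)
    i, j = np.unravel_index(flat_idx, rate.shape)
    i0, i1 = max(i - 1, 0), min(i + 2, rate.shape[0])
    j0, j1 = max(j - 1, 0), min(j + 2, rate.shape[1])
    block = rate[i0:i1, j0:j1]
    return float(np.nanmean(block))


def firing_stats(
    spike_times: np.ndarray,
    traj: TrajectorySample,
    rate_map: RateMap | None = None,
    arena: ArenaSpec | None = None,
    isi_bin: float = 1e-3,
) -> FiringStats:
    """Mean rate, instantaneous frequency and spatial coverage.

    Mean rate is spike count over session duration; instantaneous frequency
    is the reciprocal of the peak (modal) interspike interval from a 1-ms ISI
    histogram (undefined with < 2 spikes); coverage is the fraction of
    arena-interior pixels visited.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    duration = traj.duration
    mean_rate = len(spike_times) / duration

    inst = None
    if len(spike_times) >= 2:
        isis = np.diff(np.sort(spike_times))
        isis = isis[isis > 0]
        if isis.size:
            edges = np.arange(0.0, isis.max() + 2 * isi_bin, isi_bin)
            hist, _ = np.histogram(isis, bins=edges)
            mode_idx = int(np.argmax(hist))
            # bins are [k, k+1) ms; an ISI of exactly 100 ms maps to 10 Hz
            peak_isi = max(edges[mode_idx], isi_bin)
            inst = 1.0 / peak_isi

    arena = arena or ArenaSpec()
    occ = (
        rate_map.occupancy
        if rate_map is not None
        else compute_occupancy(traj, arena, speed_threshold=0.0)
    )
    n = occ.grid.shape[0]
    centers = (occ.edges_x[:-1] + occ.edges_x[1:]) / 2.0
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    interior = cx**2 + cy**2 <= arena.radius**2
    coverage = float(occ.visited_mask[interior].sum() / max(interior.sum(), 1))
    return FiringStats(
        mean_rate=float(mean_rate),
        instantaneous_freq=inst,
        coverage=coverage,
        n_spikes=len(spike_times),
    )
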