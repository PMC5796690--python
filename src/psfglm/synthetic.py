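"""Synthetic foraging sessions with known ground-truth encoding.

Generates (i) smooth open-field trajectories in a circular arena via an
Ornstein-Uhlenbeck velocity process, (ii) ground-truth cells defined by a
Gaussian place field, a post-spike filter (PSF) on the raised-cosine basis
and gain parameters, and (iii) 1-ms binned spike trains drawn from the
conditional intensity

    lambda(t) = exp(alpha0 + alpha1 * p(x(t), y(t)) + sum_spikes f_beta(t - t_spike))

updated causally from the emitted spikes.  Every downstream stage of the
package (place-field estimation, GLM fitting, feature extraction, clustering,
regression) can therefore be validated by parameter recovery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .basis import RaisedCosineBasis, build_basis

__all__ = [
    "ArenaSpec",
    "TrajectorySample",
    "GroundTruthCell",
    "BinnedSpikeTrain",
    "SimulationUnstableWarning",
    "simulate_trajectory",
    "make_ground_truth_psf",
    "simulate_spike_train",
    "simulate_from_intensity",
    "generate_population",
    "resample_position",
    "write_position_csv",
    "write_spikes_csv",
    "write_ground_truth_json",
]

CLIP_TOLERANCE = 1e-3  # max tolerated fraction of bins with lambda*delta > 1


class SimulationUnstableWarning(UserWarning):
    """Raised when the Bernoulli clipping fraction exceeds tolerance."""


@dataclass(frozen=True)
class ArenaSpec:
    """Circular open-field arena.

    diameter and bin_size in cm; wall_policy controls how the trajectory
    simulator handles excursions beyond the wall.
    """

    diameter: float = 75.0
    bin_size: float = 2.5
    wall_policy: Literal["reflect", "resample"] = "reflect"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("arena diameter must be positive")
        if not (0 < self.bin_size < self.diameter):
            raise ValueError("bin_size must be in (0, diameter)")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class TrajectorySample:
    """Time-stamped 2D positions (cm, arena-centered) with derived speeds."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.speed) == n):
            raise ValueError("t, x, y, speed must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def truncate(self, duration: float) -> "TrajectorySample":
        keep = self.t <= self.t[0] + duration
        return TrajectorySample(
            self.t[keep], self.x[keep], self.y[keep], self.speed[keep]
        )


@dataclass
class GroundTruthCell:
    """Generating parameters of one synthetic cell.

    The place field is a sum of Gaussian bumps; ``alpha0`` is the log
    baseline rate (log Hz), ``alpha1`` scales the (standardized) place
    covariate, and ``psf_beta`` holds the 11 PSF coefficients (10 smooth +
    1 impulse) on the raised-cosine basis.
    """

    field_centers: np.ndarray  # (n_fields, 2) cm
    field_widths: np.ndarray  # (n_fields,) cm
    field_gains: np.ndarray  # (n_fields,) dimensionless
    psf_beta: np.ndarray  # (11,)
    alpha0: float
    alpha1: float
    profile: str = "bursty"
    theta_freq: float = 9.0
    cell_id: int = 0
    unstable: bool = False  # set if clipped-bin fraction exceeded tolerance

    def __post_init__(self) -> None:
        self.field_centers = np.atleast_2d(np.asarray(self.field_centers, float))
        self.field_widths = np.atleast_1d(np.asarray(self.field_widths, float))
        self.field_gains = np.atleast_1d(np.asarray(self.field_gains, float))
        self.psf_beta = np.asarray(self.psf_beta, float)
        if np.any(self.field_widths <= 0):
            raise ValueError("field widths must be positive")
        if not np.all(np.isfinite(self.psf_beta)):
            raise ValueError("psf_beta must be finite")

    def place_map(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Ground-truth place-field value at positions (cm)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        out = np.zeros(np.broadcast(x, y).shape, dtype=float)
        for (cx, cy), w, g in zip(
            self.field_centers, self.field_widths, self.field_gains
        ):
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            out += g * np.exp(-0.5 * d2 / w**2)
        return out


@dataclass(frozen=True)
class BinnedSpikeTrain:
    """Binary spike sequence r(t) on the 1-ms lattice."""

    counts: np.ndarray  # uint8 0/1
    delta: float = 1e-3
    clipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.size and not np.all((c == 0) | (c == 1)):
            raise ValueError("counts must be binary")

    @property
    def duration(self) -> float:
        return len(self.counts) * self.delta

    @property
    def n_spikes(self) -> int:
        return int(self.counts.sum())

    @property
    def spike_times(self) -> np.ndarray:
        """Spike times in seconds (bin centers)."""
        return (np.nonzero(self.counts)[0] + 0.5) * self.delta

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.duration


def simulate_trajectory(
    arena: ArenaSpec,
    duration: float,
    mean_speed: float = 15.0,
    seed: int = 0,
    dt: float = 0.02,
    tau: float = 1.0,
) -> TrajectorySample:
    """Ornstein-Uhlenbeck foraging path confined to the arena.

    The velocity follows a 2D OU process with relaxation time ``tau`` (s),
    calibrated so the time-averaged speed matches ``mean_speed`` (cm/s);
    positions exceeding the wall are reflected back inside.
    Deterministic given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if mean_speed < 0:
        raise ValueError("mean_speed must be non-negative")

    rng = np.random.default_rng(seed)
    n = int(round(duration / dt)) + 1
    R = arena.radius

    # per-component stationary SD such that E|v| = sigma_v * sqrt(pi/2)
    sigma_v = mean_speed / np.sqrt(np.pi / 2.0)
    a = np.exp(-dt / tau)
    b = sigma_v * np.sqrt(1.0 - a * a)
    noise = rng.standard_normal((n - 1, 2))

    # start well inside the arena
    start_r = 0.5 * R * np.sqrt(rng.random())
    start_phi = 2 * np.pi * rng.random()
    pos = np.empty((n, 2))
    pos[0] = start_r * np.array([np.cos(start_phi), np.sin(start_phi)])
    vel = sigma_v * rng.standard_normal(2) if sigma_v > 0 else np.zeros(2)

    for i in range(1, n):
        vel = a * vel + b * noise[i - 1]
        p = pos[i - 1] + vel * dt
        r = np.hypot(p[0], p[1])
        if r > R:
            if arena.wall_policy == "reflect":
                # fold the overshoot back across the wall, reverse radial velocity
                p *= (2 * R - r) / r
                u = p / np.hypot(p[0], p[1])
                vel = vel - 2.0 * np.dot(vel, u) * u
            else:  # resample: retry the step toward the interior
                p = pos[i - 1]
                vel = -vel
        pos[i] = p

    t = np.arange(n) * dt
    disp = np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1])) / dt
    speed = np.concatenate([[disp[0] if n > 1 else 0.0], disp])
    return TrajectorySample(t=t, x=pos[:, 0], y=pos[:, 1], speed=speed)


def resample_position(
    traj: TrajectorySample, delta: float = 1e-3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear-interpolate positions onto the 1-ms spike-train lattice.

    Returns (t_bins, x, y) where t_bins are bin centers spanning the
    trajectory duration.
    """
    n_bins = int(round(traj.duration / delta))
    tb = traj.t[0] + (np.arange(n_bins) + 0.5) * delta
    return tb, np.interp(tb, traj.t, traj.x), np.interp(tb, traj.t, traj.y)


def make_ground_truth_psf(
    profile: Literal["bursty", "refractory", "flat"],
    basis: RaisedCosineBasis,
    theta_freq: float = 9.0,
    burst_gain: float = 0.9,
    theta_gain: float = 0.5,
    impulse: float = -4.0,
    burst_tau: float = 0.012,
) -> np.ndarray:
    """PSF coefficients producing a requested firing phenotype.

    The target smooth shape is a fast lobe over the first ~30 ms (a
    difference of exponentials peaking near 6 ms with unit peak height,
    scaled by ``burst_gain``: positive for bursty cells, a monotone negative
    exponential for refractory cells) plus a theta-frequency cosine tapered
    to zero at very short lags; the coefficients are the least-squares
    projection of that shape onto the smooth basis columns.  ``flat``
    returns all-zero coefficients (Poisson-like cell with no history
    dependence).  The default gains keep the self-exciting intensity
    comfortably sub-critical under the exponential link.
    """
    if profile == "flat":
        return np.zeros(basis.n_functions)
    if theta_gain != 0 and not (6.0 <= theta_freq <= 12.0):
        raise ValueError("theta_freq must lie in [6, 12] Hz when theta_gain != 0")

    s = basis.grid
    if profile == "bursty":
        lobe = np.exp(-s / burst_tau) - np.exp(-s / (burst_tau / 3.0))
        lobe = burst_gain * lobe / lobe.max()
    elif profile == "refractory":
        lobe = -burst_gain * np.exp(-s / burst_tau)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    taper = 1.0 - np.exp(-((s / 0.04) ** 2))
    target = lobe + theta_gain * taper * np.cos(2 * np.pi * theta_freq * s)

    beta_smooth, *_ = np.linalg.lstsq(basis.smooth, target, rcond=None)
    beta = np.concatenate([beta_smooth, [impulse]])
    return beta


def simulate_from_intensity(
    base_log_rate: np.ndarray,
    psf_values: np.ndarray,
    delta: float,
    seed: int,
) -> BinnedSpikeTrain:
    """Draw a binary train from lambda(t) = exp(base(t) + spike history).

    ``base_log_rate`` is the history-free log intensity (log Hz) per 1-ms
    bin; ``psf_values`` is f_beta on the lag grid, added causally to the
    log intensity of the bins following each emitted spike (the first entry
    lands on the bin immediately after the spike).  Per-bin emission is
    Bernoulli with p = min(lambda * delta, 1); the clipped-bin fraction is
    recorded and a stability warning is raised if it exceeds 0.1%.

    The per-bin uniforms are drawn up-front from ``seed``, so truncating the
    session reproduces the prefix of the longer simulation bit-for-bit.
    """
    base = np.asarray(base_log_rate, dtype=float)
    if not np.all(np.isfinite(base) | (base == -np.inf)):
        raise ValueError("non-finite log intensity in simulation")
    T = base.size
    f = np.asarray(psf_values, dtype=float)
    L = f.size
    rng = np.random.default_rng(seed)
    u = rng.random(T)

    log_lam = base.copy()
    counts = np.zeros(T, dtype=np.uint8)
    n_clipped = 0
    log_clip = -np.log(delta)  # lambda*delta > 1  <=>  log lambda > -log delta

    chunk = 2048
    t = 0
    while t < T:
        b = min(t + chunk, T)
        seg = log_lam[t:b]
        with np.errstate(over="ignore"):  # overflow -> inf -> p clipped at 1
            p = np.exp(seg) * delta
        hit = np.nonzero(u[t:b] < np.minimum(p, 1.0))[0]
        if hit.size == 0:
            n_clipped += int(np.count_nonzero(seg > log_clip))
            t = b
            continue
        s_idx = t + int(hit[0])
        n_clipped += int(np.count_nonzero(log_lam[t : s_idx + 1] > log_clip))
        counts[s_idx] = 1
        hi = min(s_idx + 1 + L, T)
        log_lam[s_idx + 1 : hi] += f[: hi - (s_idx + 1)]
        t = s_idx + 1

    frac = n_clipped / max(T, 1)
    if frac > CLIP_TOLERANCE:
        warnings.warn(
            f"lambda*delta clipped at 1 in {frac:.2%} of bins "
            f"(tolerance {CLIP_TOLERANCE:.2%}); intensity model is unstable",
            SimulationUnstableWarning,
            stacklevel=2,
        )
    return BinnedSpikeTrain(counts=counts, delta=delta, clipped_fraction=frac)


def standardize_covariate(p: np.ndarray) -> np.ndarray:
    """Z-score a place covariate; constant covariates map to zero."""
    p = np.asarray(p, dtype=float)
    sd = p.std()
    if sd == 0:
        return np.zeros_like(p)
    return (p - p.mean()) / sd


def _arena_field_peak(
    cell: GroundTruthCell, arena: ArenaSpec, n_grid: int = 121
) -> float:
    """Peak of the ground-truth field over the arena interior.

    The simulation covariate is the field divided by this peak, so it lies
    in [0, 1] and alpha1 is the log of the in-field gain.  The constant
    depends only on the cell and arena, never on session length, so
    truncating a session reproduces the prefix of the longer simulation
    (causality of the emission process).
    """
    g = np.linspace(-arena.radius, arena.radius, n_grid)
    gx, gy = np.meshgrid(g, g)
    inside = gx**2 + gy**2 <= arena.radius**2
    peak = float(cell.place_map(gx[inside], gy[inside]).max())
    return peak if peak > 0 else 1.0


def simulate_spike_train(
    traj: TrajectorySample,
    cell: GroundTruthCell,
    basis: RaisedCosineBasis,
    seed: int,
    delta: float = 1e-3,
    place_covariate: np.ndarray | None = None,
    arena: ArenaSpec | None = None,
) -> BinnedSpikeTrain:
    """Emit a 1-ms binned train from the cell's conditional intensity.

    The trajectory is resampled to the 1-ms lattice; the place covariate is
    the cell's ground-truth field evaluated along the path, peak-normalized
    to [0, 1] with an arena-wide constant (so the covariate at time t never
    depends on the future of the session); alpha1 is then the log in-field
    gain.  Pass ``place_covariate`` to override (e.g. with a fitted
    rate-map covariate).
    """
    if place_covariate is None:
        arena = arena or ArenaSpec()
        _, xb, yb = resample_position(traj, delta)
        place_covariate = cell.place_map(xb, yb) / _arena_field_peak(cell, arena)
    base = cell.alpha0 + cell.alpha1 * np.asarray(place_covariate, dtype=float)
    psf_values = basis.expand(cell.psf_beta)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", SimulationUnstableWarning)
        train = simulate_from_intensity(base, psf_values, delta, seed)
    for w in caught:
        if issubclass(w.category, SimulationUnstableWarning):
            cell.unstable = True
        warnings.warn_explicit(
            w.message, w.category, w.filename, w.lineno
        )
    return train


def _default_param_ranges(profile: str = "bursty") -> dict:
    """Per-profile generating ranges.

    Bursty cells are self-exciting under the exponential link, so their
    theta gain and in-field peak rate are kept low enough that the
    effective branching ratio stays well below criticality; refractory
    cells are self-damping and can fire faster (which also gives their
    weaker-SNR filters enough spikes to be recoverable).
    """
    common = {
        "theta_freq": (8.0, 9.5),
        "field_width": (6.0, 12.0),
        "n_fields": (1, 2),
        "burst_gain": (0.8, 1.1),
    }
    if profile == "refractory":
        return {
            **common,
            "theta_gain": (0.3, 0.5),
            "alpha0": (np.log(1.5), np.log(2.2)),
            "alpha1": (1.2, 1.8),
        }
    return {
        **common,
        "burst_gain": (0.6, 0.75),
        "theta_gain": (0.25, 0.3),
        "alpha0": (np.log(2.2), np.log(2.8)),
        "alpha1": (0.6, 0.75),
    }


def generate_population(
    n_cells: int,
    group_spec: Sequence[dict] | None = None,
    seed: int = 0,
    arena: ArenaSpec | None = None,
    duration: float = 900.0,
    mean_speed: float = 15.0,
    basis: RaisedCosineBasis | None = None,
    shared_trajectory: bool = True,
) -> list[tuple[GroundTruthCell, BinnedSpikeTrain, TrajectorySample]]:
    """Reproducible cohort of ground-truth cells with emitted spike trains.

    ``group_spec`` is a list of mixture components, each a dict with a
    ``profile`` ("bursty" | "refractory" | "flat"), a ``fraction`` of the
    population, and optional parameter-range overrides.  Cell counts per
    component are allocated deterministically (largest-remainder rounding),
    and each cell consumes an independent substream spawned from the master
    seed, so populations are bit-reproducible and order-independent.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if group_spec is None:
        group_spec = [
            {"profile": "bursty", "fraction": 0.8},
            {"profile": "refractory", "fraction": 0.2},
        ]
    if len(group_spec) == 0:
        raise ValueError("group_spec mixture must be non-empty")
    arena = arena or ArenaSpec()
    basis = basis or build_basis()

    fracs = np.array([g.get("fraction", 1.0 / len(group_spec)) for g in group_spec])
    fracs = fracs / fracs.sum()
    counts = np.floor(fracs * n_cells).astype(int)
    remainder = fracs * n_cells - counts
    for i in np.argsort(-remainder)[: n_cells - counts.sum()]:
        counts[i] += 1

    master = np.random.SeedSequence(seed)
    traj_ss, *cell_ss = master.spawn(n_cells + 1)
    shared_traj = (
        simulate_trajectory(
            arena, duration, mean_speed, seed=traj_ss.generate_state(1)[0] % 2**31
        )
        if shared_trajectory
        else None
    )

    out: list[tuple[GroundTruthCell, BinnedSpikeTrain, TrajectorySample]] = []
    cell_id = 0
    for comp, n_comp in zip(group_spec, counts):
        ranges = {**_default_param_ranges(comp["profile"]), **comp.get("params", {})}
        for _ in range(n_comp):
            ss = cell_ss[cell_id]
            rng = np.random.default_rng(ss)
            sim_seed = int(ss.generate_state(2)[1] % 2**31)
            traj = shared_traj or simulate_trajectory(
                arena, duration, mean_speed, seed=sim_seed ^ 0x5EED
            )
            cell = _draw_cell(rng, comp["profile"], ranges, arena, basis, cell_id)
            train = simulate_spike_train(traj, cell, basis, seed=sim_seed, arena=arena)
            out.append((cell, train, traj))
            cell_id += 1
    return out


def _draw_cell(
    rng: np.random.Generator,
    profile: str,
    ranges: dict,
    arena: ArenaSpec,
    basis: RaisedCosineBasis,
    cell_id: int,
) -> GroundTruthCell:
    lo, hi = ranges["n_fields"]
    n_fields = int(rng.integers(lo, hi + 1))
    r = arena.radius * 0.7 * np.sqrt(rng.random(n_fields))
    phi = 2 * np.pi * rng.random(n_fields)
    centers = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    widths = rng.uniform(*ranges["field_width"], size=n_fields)
    gains = np.ones(n_fields)
    theta_freq = float(rng.uniform(*ranges["theta_freq"]))
    beta = make_ground_truth_psf(
        profile,
        basis,
        theta_freq=theta_freq,
        burst_gain=float(rng.uniform(*ranges["burst_gain"])),
        theta_gain=float(rng.uniform(*ranges["theta_gain"])),
    )
    return GroundTruthCell(
        field_centers=centers,
        field_widths=widths,
        field_gains=gains,
        psf_beta=beta,
        alpha0=float(rng.uniform(*ranges["alpha0"])),
        alpha1=float(rng.uniform(*ranges["alpha1"])),
        profile=profile,
        theta_freq=theta_freq,
        cell_id=cell_id,
    )


# ---------------------------------------------------------------------------
# plain-text writers


def write_position_csv(traj: TrajectorySample, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"t_s": traj.t, "x_cm": traj.x, "y_cm": traj.y}).to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


def write_spikes_csv(
    trains: dict[int, BinnedSpikeTrain] | dict[int, np.ndarray], path: str | Path
) -> Path:
    rows = []
    for cid, tr in trains.items():
        times = tr.spike_times if isinstance(tr, BinnedSpikeTrain) else np.asarray(tr)
        rows.append(pd.DataFrame({"cell_id": cid, "t_s": times}))
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["cell_id", "t_s"])
    )
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.4f")
    return path


def write_ground_truth_json(
    cells: Sequence[GroundTruthCell], path: str | Path
) -> Path:
    payload = []
    for c in cells:
        d = asdict(c)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        payload.append(d)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path
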