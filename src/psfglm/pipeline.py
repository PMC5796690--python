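"""End-to-end pipeline: simulate/load -> place fields -> GLM -> features ->
clustering -> regression, with plain-text artifacts and a run manifest.

Each stage writes delimited-text or JSON outputs into the run directory and
records its files (with SHA-256 checksums) in the manifest, so deterministic
stages can be verified to reproduce bit-identically.  A failure on one cell
(e.g. too few spikes to fit) is logged and the cell skipped; the pipeline
completes on the remaining cells.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import glm as glm_mod
from . import maps as maps_mod
from . import population as pop_mod
from .basis import build_basis
from .synthetic import (
    ArenaSpec,
    BinnedSpikeTrain,
    TrajectorySample,
    generate_population,
    write_ground_truth_json,
    write_position_csv,
    write_spikes_csv,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "read_session"]

logger = logging.getLogger("psfglm")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; round-trips through YAML."""

    outdir: str = "psfglm_run"
    seed: int = 0
    # synthetic session
    synthetic: bool = True
    n_cells: int = 20
    duration: float = 900.0
    mean_speed: float = 15.0
    arena_diameter: float = 75.0
    bursty_fraction: float = 0.8
    # inputs when synthetic=False
    position_path: str | None = None
    spikes_path: str | None = None
    # spatial maps
    bin_size: float = 2.5
    bandwidth: float = 5.0
    cv_bandwidths: list[float] = field(default_factory=list)  # empty = fixed
    cv_folds: int = 5
    speed_threshold: float = 5.0
    coherence_threshold: float = 0.3
    coherence_fisher_z: bool = True
    # GLM
    n_smooth: int = 10
    psf_duration: float = 0.7
    delta: float = 1e-3
    warp_offset: float = 0.015
    xi: float = 1.0
    xi_grid: list[float] = field(default_factory=list)  # empty = fixed xi
    # clustering / regression
    kmeans_restarts: int = 50
    regression_interactions: bool = True
    min_spikes: int = 50

    def validate(self) -> None:
        for name in ("bin_size", "bandwidth", "coherence_threshold", "xi", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.speed_threshold < 0:
            raise ValueError("speed_threshold must be non-negative")
        if not self.synthetic and not (self.position_path and self.spikes_path):
            raise ValueError(
                "synthetic generation disabled but no input paths given"
            )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    started: str
    finished: str = ""
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256
    warnings: list[str] = field(default_factory=list)
    skipped_cells: dict[str, str] = field(default_factory=dict)

    def record(self, path: Path) -> None:
        self.artifacts[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))


def read_session(
    position_path: str | Path,
    spikes_path: str | Path,
    delta: float = 1e-3,
) -> tuple[TrajectorySample, dict[int, BinnedSpikeTrain]]:
    """Load a recorded session from the package's CSV schemas.

    Position: columns ``t_s, x_cm, y_cm`` with strictly increasing, uniform
    timestamps.  Spikes: columns ``cell_id, t_s``.  Positions are validated,
    speeds derived, and each cell's spike times are binned onto the 1-ms
    lattice spanning the trajectory.  Spikes falling after the trajectory
    end are rejected with their count reported.
    """
    pos = pd.read_csv(position_path)
    for col in ("t_s", "x_cm", "y_cm"):
        if col not in pos.columns:
            raise ValueError(f"position file missing column {col!r}")
    t = pos["t_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("position file needs at least 2 samples")
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-monotone timestamps at rows {(bad + 2).tolist()[:5]}"
        )
    if np.ptp(dt) > 1e-6 * dt.mean():
        raise ValueError("position timestamps must be uniformly spaced")
    x = pos["x_cm"].to_numpy(float)
    y = pos["y_cm"].to_numpy(float)
    disp = np.hypot(np.diff(x), np.diff(y)) / dt
    speed = np.concatenate([[disp[0]], disp])
    traj = TrajectorySample(t=t, x=x, y=y, speed=speed)

    spk = pd.read_csv(spikes_path)
    for col in ("cell_id", "t_s"):
        if col not in spk.columns:
            raise ValueError(f"spikes file missing column {col!r}")
    n_bins = int(round(traj.duration / delta))
    trains: dict[int, BinnedSpikeTrain] = {}
    for cid, grp in spk.groupby("cell_id"):
        st = np.sort(grp["t_s"].to_numpy(float)) - traj.t[0]
        late = st > traj.duration
        if late.any():
            logger.warning(
                "cell %s: %d spikes beyond trajectory end rejected",
                cid,
                int(late.sum()),
            )
        st = st[(st >= 0) & ~late]
        counts = np.zeros(n_bins, dtype=np.uint8)
        idx = np.minimum((st / delta).astype(int), n_bins - 1)
        counts[idx] = 1  # binary trains: coincident spikes in a bin collapse
        trains[int(cid)] = BinnedSpikeTrain(counts=counts, delta=delta)
    return traj, trains


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage and return the populated manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    logfile = outdir / "run.log"
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        _run_stages(config, outdir, manifest)
    finally:
        logger.removeHandler(handler)
        handler.close()
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return manifest


def _run_stages(config: PipelineConfig, outdir: Path, manifest: RunManifest) -> None:
    arena = ArenaSpec(diameter=config.arena_diameter, bin_size=config.bin_size)
    basis = build_basis(
        n_smooth=config.n_smooth,
        duration=config.psf_duration,
        delta=config.delta,
        warp_offset=config.warp_offset,
    )
    config.to_yaml(outdir / "config.yaml")
    manifest.record(outdir / "config.yaml")

    # --- stage: data -------------------------------------------------------
    ground_truth = {}
    if config.synthetic:
        spec = [
            {"profile": "bursty", "fraction": config.bursty_fraction},
            {"profile": "refractory", "fraction": 1 - config.bursty_fraction},
        ]
        pop = generate_population(
            config.n_cells,
            spec,
            seed=config.seed,
            arena=arena,
            duration=config.duration,
            mean_speed=config.mean_speed,
            basis=basis,
        )
        traj = pop[0][2]
        trains = {c.cell_id: tr for c, tr, _ in pop}
        ground_truth = {c.cell_id: c for c, _, _ in pop}
        write_position_csv(traj, outdir / "position.csv")
        write_spikes_csv(trains, outdir / "spikes.csv")
        write_ground_truth_json(
            [c for c, _, _ in pop], outdir / "ground_truth.json"
        )
        for name in ("position.csv", "spikes.csv", "ground_truth.json"):
            manifest.record(outdir / name)
    else:
        traj, trains = read_session(
            config.position_path, config.spikes_path, config.delta
        )
    logger.info("session loaded: %d cells, %.0f s", len(trains), traj.duration)

    # --- per-cell stages ---------------------------------------------------
    rows = []
    curves = {}
    for cid, train in trains.items():
        try:
            row, curve = _process_cell(cid, train, traj, arena, basis, config)
        except Exception as exc:  # degenerate cells are skipped, not fatal
            logger.warning("cell %s skipped: %s", cid, exc)
            manifest.skipped_cells[str(cid)] = str(exc)
            continue
        if config.synthetic and cid in ground_truth:
            row["true_profile"] = ground_truth[cid].profile
        rows.append(row)
        curves[cid] = curve
    if not rows:
        raise ValueError("no cell could be processed")
    table = pd.DataFrame(rows).set_index("cell_id")
    curve_df = pd.DataFrame(
        {cid: c for cid, c in curves.items()}
    ).T.sort_index()
    curve_df.columns = [f"t{int(ms)}" for ms in range(curve_df.shape[1])]

    # --- population stages -------------------------------------------------
    fnorm = curve_df.to_numpy()
    if len(table) >= 2:
        cluster = pop_mod.cluster_psfs(
            fnorm,
            seed=config.seed,
            n_init=config.kmeans_restarts,
            burstiness_values=table["burstiness"].to_numpy(),
        )
        table["cluster"] = cluster.labels
    if len(table) >= 3 and table["coherence"].nunique() > 1:
        feature_cols = list(feat.PSFFeatures.FEATURE_NAMES)
        reg = pop_mod.regress_coherence(
            table[feature_cols],
            table["coherence"].to_numpy(),
            interactions=config.regression_interactions,
        )
        (outdir / "regression.json").write_text(
            json.dumps(
                {
                    "spearman_r2": reg.spearman_r2,
                    "pearson_r2": reg.pearson_r2,
                    "coefficients": reg.coefficients.to_dict(),
                },
                indent=1,
            )
        )
        manifest.record(outdir / "regression.json")
        corr = pop_mod.timepoint_coherence_correlation(
            fnorm, table["coherence"].to_numpy()
        )
        pd.DataFrame(
            {"lag_ms": np.arange(corr.size), "spearman_r": corr}
        ).to_csv(outdir / "coherence_correlation.csv", index=False)
        manifest.record(outdir / "coherence_correlation.csv")

    table.to_csv(outdir / "features.csv", float_format="%.6g")
    curve_df.to_csv(outdir / "psf_curves.csv", float_format="%.6g")
    manifest.record(outdir / "features.csv")
    manifest.record(outdir / "psf_curves.csv")
    logger.info("pipeline complete: %d cells in feature table", len(table))


def _process_cell(
    cid: int,
    train: BinnedSpikeTrain,
    traj: TrajectorySample,
    arena: ArenaSpec,
    basis,
    config: PipelineConfig,
) -> tuple[dict, np.ndarray]:
    if train.n_spikes < config.min_spikes:
        raise ValueError(
            f"{train.n_spikes} spikes < min_spikes={config.min_spikes}"
        )
    st = train.spike_times
    bw = config.bandwidth
    if config.cv_bandwidths:
        bw = maps_mod.select_bandwidth_cv(
            st,
            traj,
            np.asarray(config.cv_bandwidths),
            folds=config.cv_folds,
            bin_size=config.bin_size,
            arena=arena,
            speed_threshold=config.speed_threshold,
        )
    rmap = maps_mod.compute_rate_map(
        st,
        traj,
        bin_size=config.bin_size,
        bandwidth=bw,
        arena=arena,
        speed_threshold=config.speed_threshold,
    )
    coherence = maps_mod.compute_coherence(rmap, fisher_z=config.coherence_fisher_z)
    stats_ = maps_mod.firing_stats(st, traj, rate_map=rmap, arena=arena)

    _, xb, yb = _resample(traj, config.delta, train.counts.size)
    p_cov = rmap.covariate_at(xb, yb)
    sd = p_cov.std()
    p_cov = (p_cov - p_cov.mean()) / sd if sd > 0 else np.zeros_like(p_cov)

    if config.xi_grid:
        xi, fits = glm_mod.select_ridge(
            train, p_cov, basis, np.asarray(config.xi_grid), return_fits=True
        )
        fit = fits[xi]
    else:
        fit = glm_mod.fit_glm(train, p_cov, basis, xi=config.xi)
    psf = glm_mod.evaluate_psf(fit, basis)
    f = feat.extract_features(psf, mean_rate=stats_.mean_rate)
    fn = feat.normalize_unit_power(psf)

    row = {
        "cell_id": cid,
        "mean_rate": stats_.mean_rate,
        "instantaneous_freq": stats_.instantaneous_freq,
        "coverage": stats_.coverage,
        "bandwidth": bw,
        "peak_rate": rmap.peak_rate,
        "coherence": coherence,
        "is_place_cell": maps_mod.classify_place_cell(
            coherence, config.coherence_threshold
        ),
        "alpha0": fit.alpha0,
        "alpha1": fit.alpha1,
        "xi": fit.xi,
        "converged": fit.converged,
        **f.as_dict(),
    }
    return row, fn.values


def _resample(traj: TrajectorySample, delta: float, n_bins: int):
    tb = traj.t[0] + (np.arange(n_bins) + 0.5) * delta
    return tb, np.interp(tb, traj.t, traj.x), np.interp(tb, traj.t, traj.y)
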