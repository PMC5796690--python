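"""Fit the point-process GLM and recover a known post-spike filter.

Simulates a bursty, theta-modulated cell, fits the penalized GLM (place
covariate + 11 raised-cosine history coefficients), selects the ridge
penalty by evidence maximization, and compares the fitted smooth PSF with
the generating one.
"""

import numpy as np

from psfglm import (
    ArenaSpec,
    GroundTruthCell,
    build_basis,
    evaluate_psf,
    fit_glm,
    make_ground_truth_psf,
    select_ridge,
    simulate_spike_train,
    simulate_trajectory,
)
from psfglm.synthetic import _arena_field_peak, resample_position

arena = ArenaSpec()
basis = build_basis()
traj = simulate_trajectory(arena, duration=900.0, mean_speed=15.0, seed=5)

beta_true = make_ground_truth_psf("bursty", basis, theta_freq=9.0)
cell = GroundTruthCell(
    field_centers=[[5.0, -3.0]], field_widths=[9.0], field_gains=[1.0],
    psf_beta=beta_true, alpha0=np.log(2.5), alpha1=0.7, profile="bursty",
)
train = simulate_spike_train(traj, cell, basis, seed=6)
print(f"simulated bursty cell: {train.n_spikes} spikes ({train.mean_rate:.2f} Hz)")

_, xb, yb = resample_position(traj)
p_raw = cell.place_map(xb, yb) / _arena_field_peak(cell, arena)
sigma_p = p_raw.std()
p = (p_raw - p_raw.mean()) / sigma_p  # fitting convention: z-scored covariate

xi = select_ridge(train, p, basis)
print(f"evidence-selected ridge penalty: xi = {xi:.3g}")

fit = fit_glm(train, p, basis, xi=xi)
print(f"fit converged in {fit.n_iter} Newton iterations "
      f"(|grad| = {fit.gradient_norm:.1e})")
# rescale the fitted gain from per-SD to per-unit-field for comparison
print(f"place-field log-gain: fitted {fit.alpha1 / sigma_p:.3f} per unit field "
      f"(true {cell.alpha1:.3f})")

psf = evaluate_psf(fit, basis)
true_smooth = basis.expand_smooth(beta_true)
r = np.corrcoef(psf.smooth_component, true_smooth)[0, 1]
print(f"correlation(true, fitted smooth PSF) = {r:.3f}")
print(f"post-spike gain at 3 ms: {np.exp(psf.values[3]):.2f}x; "
      f"at one theta cycle (111 ms): {np.exp(psf.values[111]):.2f}x")
# A correlation above 0.9 means the fitted filter reproduces both the
# immediate burst up-regulation and the theta-timescale modulation.
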