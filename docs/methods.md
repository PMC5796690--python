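# Methods

## Model

The spike train of one cell, binned at Δ = 1 ms into a binary sequence
r(t), is modeled as a self-exciting point process with conditional intensity

    λ(t) = exp( α₀ + α₁ p(x(t), y(t)) + Σ_{τ<t} r(τ) f_β(t − τ) )

- **α₀** — log baseline rate (log Hz).
- **p(x, y)** — the place-field covariate. The map is estimated *before*
  the GLM (smoothed rate map, below), sampled along the trajectory on the
  1-ms lattice, and z-scored over bins; it is never refit inside the GLM.
  The exponent α₁·p is scale-fragile if p enters in Hz, and standardization
  makes the fit numerically stable and α₁ comparable across cells. (The
  simulator's ground-truth covariate is instead peak-normalized to [0, 1],
  so its α₁ is the log in-field gain and, crucially, the covariate at time
  t never depends on the future of the session — which makes truncation of
  a session reproduce the prefix of the longer simulation exactly.)
- **f_β(s)** — the post-spike filter (PSF) over lags s ∈ (0, 0.7] s,
  parametrized as f_β = Σᵢ₌₁¹⁰ βᵢ bᵢ(s) + β₁₁ b₁₁(s). The bᵢ are
  raised-cosine bumps with centers equi-spaced in warped time
  u = log(s + ψ), ψ = 15 ms by default, tiling the support; b₁₁ is the
  indicator of the first 1-ms bin and absorbs the absolute refractory
  period. The first ten terms are the *smooth component*. The basis matrix
  is evaluated at lags s_k = k·1 ms, k = 0..699, so the impulse is exactly
  the first bin, the theta windows (below) fall on grid points, and the
  matrix has shape (700, 11).

Fitting maximizes the penalized log-likelihood
L = Σ_t [r log(λΔ) − λΔ] − ξ‖β‖² (only β is penalized) by Newton's method
with backtracking line search (gradient tolerance 1e-8 scaled by spike
count, ≤ 200 iterations). L is strictly concave in (α₀, α₁, β) for ξ > 0,
so the optimum is unique; the analytic gradient and Hessian are exact, which
the tests verify against central finite differences (relative error ~1e-9).

**Ridge selection.** ξ is chosen from a log-spaced grid (10 points,
1e-2..1e4) by maximizing the Laplace-approximated log evidence
L(θ̂) + (11/2)·log(2ξ) − ½·log det H_β, where H_β is the β-block of the
penalized-NLL Hessian at the mode and 2ξ is the precision of the implied
Gaussian prior on β; additive constants are dropped since only grid
comparisons matter. Ties break toward the larger penalty. On history-free
Poisson data the evidence is maximized at the grid maximum (β → 0 is
correct); with genuine history structure it settles in the interior.

## Place fields and spatial statistics

Sessions are speed-filtered (samples ≥ 5 cm/s, threshold inclusive; spikes
inherit the mask of their containing position sample). Spike counts and
occupancy are binned at 2.5 cm (30×30 over a 75-cm arena), both smoothed
with the same 2D Gaussian kernel, and divided; pixels with smoothed
occupancy < 0.1 s are masked. The kernel bandwidth is selected by 5-fold
cross-validation on contiguous time blocks, scoring each candidate by the
held-out inhomogeneous-Poisson log-likelihood of the block's spike counts
given the training-blocks map; ties go to the larger bandwidth, and a
spike-free training fold scores the held-out data under the floor-rate map
rather than erroring. For a 10-cm generating field the CV optimum sits at
~5 cm — below the intrinsic field width, as bias–variance reasoning
predicts.

**Spatial coherence** is the Pearson correlation between each valid pixel's
rate and the mean rate of its valid 8-neighbors (edge pixels use the
neighbors they have), Fisher z-transformed by default (Muller–Kubie
convention); `fisher_z=False` gives the raw r, since published values in
the 0–0.9 range are consistent with either reading. Constant maps and maps
with fewer than 9 valid pixels are signalled as undefined rather than
returning a number. A cell is a "classical place cell" when coherence
≥ 0.3 (inclusive). Peak rate is the mean of the argmax pixel and its
neighbors; mean rate is count/duration; instantaneous frequency is the
reciprocal of the modal 1-ms ISI-histogram bin (left edge, so regular
100-ms spiking gives exactly 10 Hz); coverage is the visited fraction of
arena-interior pixels.

## Timing features

Features are computed on the **smooth component only**, normalized to unit
power: f_norm = f / sqrt(∫f²). The PSF is represented by its 1-ms samples
and treated as piecewise linear between them, so every integral is the
trapezoid rule on the native grid with inclusive window endpoints (the
tests check agreement with an independent 0.1-ms midpoint-Riemann
quadrature of the same representation).

- burstiness = ∫₀^{30 ms} f_norm
- theta peak = max f_norm on [83, 167] ms; theta peak time = its latency
- theta trough = min f_norm on [42, 83] ms; theta depth = peak − trough
- theta integral = ∫_{83 ms}^{250 ms} f_norm
- C_θ = max over ω ∈ [6, 12] Hz (0.05-Hz grid) of corr(f_norm, cos(2πωt))
  over the full support. A Pearson correlation is invariant to the positive
  cosine amplitude, so only ω is scanned; a constant input has C_θ = 0 by
  convention.
- rate-normalized power P(f) = r̄ · ∫ f², with r̄ the session mean rate,
  computed on the raw (unnormalized) smooth component; it compensates the
  inverse relation between per-spike modulation and firing rate.

**Known limitation — C_θ as a frequency estimator.** Ten log-spaced bumps
cannot carry oscillation phase beyond the first one-to-two theta cycles, so
on basis-projected filters the argmax-ω of C_θ deviates from the generating
frequency by up to ~1.5 Hz (verified by direct scans over theta-pure and
mixed targets for a range of warp constants and correlation windows). On
unprojected cosines the scan is exact to its 0.05-Hz step. C_θ should be
read as a theta-modulation *strength* feature, not a frequency estimate.

## Synthetic data

The generator defines the conditions under which the pipeline is validated.

- **Trajectory**: 2D Ornstein–Uhlenbeck velocity (relaxation τ = 1 s,
  per-component SD calibrated so the mean speed is 15 cm/s), integrated at
  20-ms steps for 15-min sessions, reflected at the wall of the 75-cm
  arena. A smooth, speed-tunable surrogate for open-field foraging — not a
  behavioral model: it has no home-base bias, thigmotaxis, or pause/run
  structure.
- **Cells**: 1–2 Gaussian place fields (widths 6–12 cm, centers within 70%
  of the arena radius); PSFs built per phenotype by least-squares
  projection of a target shape onto the smooth basis — bursty: a
  difference-of-exponentials lobe peaking near 6 ms (zero at s = 0) plus a
  taper-gated theta cosine; refractory: a negative exponential lobe plus
  the same theta term; impulse coefficient −4 (absolute refractoriness).
- **Emission**: per-bin Bernoulli with p = min(λΔ, 1), the history term
  updated causally from emitted spikes; per-bin uniforms are drawn up-front
  from the seed so truncated sessions reproduce prefixes. The fraction of
  clipped bins (λΔ > 1) is recorded and a warning raised above 0.1% — the
  stability audit for the self-exciting intensity.
- **Stability-driven parameter ranges.** Under the exponential link the
  process turns super-critical sharply: each in-burst spike multiplies the
  rate by e^(burst lobe), and theta feedback resonates once
  (theta gain) × (in-field rate) × (cycle length) approaches unity.
  The default generating boxes were chosen (once, by scanning the stability
  boundary) to keep the cohort comfortably sub-critical while leaving
  enough spikes for recovery: bursty cells — baseline 2.2–2.8 Hz, in-field
  log-gain 0.6–0.75, burst lobe 0.6–0.75, theta gain 0.25–0.3; refractory
  cells (self-damping, can run hotter) — baseline 1.5–2.2 Hz, log-gain
  1.2–1.8, lobe 0.8–1.1, theta gain 0.3–0.5; theta frequency 8–9.5 Hz
  (typical rat foraging theta) for both. Mixtures are allocated
  deterministically (largest remainder), and each cell consumes an
  independent counter-derived substream of the master seed.
- **What passing tests do and do not show.** Synthetic rate maps are far
  smoother than tetrode data (no sorting noise, no unsampled pixels, no
  behavioral inhomogeneity), so coherence saturates near its ceiling for
  clean place cells and the regression studies construct their coherence
  values from the features at a known signal fraction instead. Recovery
  results therefore demonstrate correctness of the estimators under the
  model, not their robustness to real-data artifacts.

## Validation studies

`psfglm.validation` packages the simulation studies run by the test suite
and by `scripts/acceptance.py`; problem sizes are the package's own choice
of a desk-scale protocol:

1. gradient exactness — 50 random small instances (1200 bins), vector-norm
   relative error vs central differences;
2. PSF recovery — 20 cells, 900-s shared session, ξ = 1 (small penalties
   recover shapes best; larger ξ biases them, which the ridge-limit test
   demonstrates separately): median correlation between true and fitted
   normalized smooth PSFs and the sign of the immediate 0–30 ms lobe;
3. ACG closure — same cohort; integrated squared error between the
   area-normalized, 10-ms-smoothed data ACG and ACGs predicted by
   simulating from the full fit vs from a place-field-only fit (6
   simulations each);
4. feature closed forms — the unit-power 9-Hz cosine (C_θ = 1, peak at
   111 ms, trough in-window), the constant unit-power filter
   (burstiness = 0.03/√0.7), and fine-grid quadrature agreement;
5. coherence sanity — 4×4 checkerboard vs an explicit 16-pixel
   computation, exact scale invariance, shuffle null;
6. clustering — 100-cell 80/20 population, ground-truth filters, k-means
   (k = 2) under correlation distance implemented as row standardization +
   Euclidean k-means (the two objectives coincide exactly), labels assigned
   by mean burstiness;
7. regression calibration — 200 bursty cells, synthetic coherence =
   standardized linear function of the theta features at signal fraction
   0.6 plus Gaussian noise; main-effects regression, predicted-vs-observed
   Spearman r² averaged over 20 noise draws (≈ 0.59 ± 0.05), and the
   noiseless exactness check (r² = 1). Interaction terms are exercised by
   the in-sample monotonicity and noiseless tests instead: with all two-way
   interactions the in-sample fit inflates beyond the generating signal
   fraction — the overfitting behavior the reduced-model comparison is
   there to expose. Note the canonical feature set is structurally
   rank-deficient (depth = peak − trough), so the regression always engages
   its documented ridge fallback (1e-6) with a warning;
8. ridge behavior — 300-s sessions; evidence selection lands on the grid
   maximum for a history-free cell and in the interior for a strong-PSF
   cell.

## Numerical and design notes

- Newton line search guarantees monotone penalized likelihood; non-PD
  Hessians (not observed in practice) fall back to a scaled gradient step.
- The design matrix column for basis function i at time t is the causal
  convolution of the spike train with bᵢ; the first basis bin weights the
  bin immediately after a spike.
- ACGs are one-sided lag histograms (default max lag 0.65 s) smoothed with
  a 10-ms boxcar; a 20-ms Gaussian variant and area normalization are
  available for cross-cell shape comparison, and the boxcar's zero-padded
  edges are excluded from flatness checks.
- Degenerate inputs are explicit: empty trains cannot be fit; < 2 spikes
  have no ACG or instantaneous frequency; constant maps have undefined
  coherence; zero-power PSFs cannot be normalized; identical PSFs cannot be
  clustered. The pipeline logs and skips such cells instead of aborting.
- k-means uses 50 restarts at a fixed seed; PCA is exact (full SVD);
  deterministic stages of the pipeline reproduce byte-identical artifacts,
  which the manifest's SHA-256 checksums make checkable.
- Coverage is reported as the visited fraction of arena-interior pixels —
  a dimensionless fraction, the one reading of "coverage" that is
  well-defined on a binned map.
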