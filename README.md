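# psfglm

Point-process GLMs that separate **place-modulated rate coding** from **fine
spike timing** in hippocampal spike trains.

Hippocampal CA1 pyramidal cells carry two kinds of structure: a spatial rate
code (the place field) and fine temporal structure on millisecond-to-theta
timescales (bursting, refractoriness, 6–12 Hz theta modulation). Raw
autocorrelograms confound the two, because slow behavioral modulation of the
firing rate also shapes spike-pair statistics. `psfglm` disentangles them
with a generalized linear model of the 1-ms binned spike train r(t):

    λ(t) = exp( α₀ + α₁ · p(x(t), y(t)) + Σ_τ r(τ) · f_β(t − τ) )

where p(x, y) is the cell's place-field map (estimated separately and
treated as a covariate), and f_β is the **post-spike filter (PSF)**: a
function of the time since each previous spike, expanded on ten
raised-cosine bumps (log-warped over 0.7 s) plus a 1-ms impulse that absorbs
the absolute refractory period. Fitting maximizes the ridge-penalized
Poisson log-likelihood

    L(α₀, α₁, β) = Σ_t [ r(t) log(λ(t)Δ) − λ(t)Δ ] − ξ‖β‖²

by Newton's method; only β is penalized and the penalty ξ is chosen on a
grid by Laplace-approximated evidence maximization.

The package is aimed at systems neuroscientists who want to phenotype firing
dynamics and relate them to spatial coding quality. It provides:

- **synthetic sessions** — Ornstein–Uhlenbeck foraging paths in a 75-cm
  arena and spike trains emitted from ground-truth conditional intensities,
  so every stage is testable by parameter recovery;
- **place-field estimation** — Gaussian-smoothed rate maps with 5-fold
  cross-validated bandwidth, speed filtering (≥ 5 cm/s), and **spatial
  coherence** (correlation of each pixel with its 8 neighbors, Fisher
  z-transformed; coherence ≥ 0.3 is the classical place-cell criterion);
- **the GLM core** — penalized fitting, evidence-based ridge selection, PSF
  evaluation, and model-predicted autocorrelograms;
- **timing features** — burstiness (0–30 ms integral of the unit-power
  PSF), theta peak/latency/trough/depth, theta cosine correlation C_θ
  (frequency scanned over 6–12 Hz), theta integral, rate-normalized power;
- **population analyses** — PCA of PSFs, k-means (k = 2, correlation
  distance) clustering into bursty vs refractory phenotypes, per-lag
  correlation of the PSF with coherence, multivariable regression of
  coherence on timing features (with two-way interactions), Cohen's d.

## Worked example

Fit the GLM to a simulated bursty, theta-modulated cell and recover its
post-spike filter (`examples/03_fit_glm_psf.py`):

```bash
$ python examples/03_fit_glm_psf.py
simulated bursty cell: 2859 spikes (3.18 Hz)
evidence-selected ridge penalty: xi = 1
fit converged in 6 Newton iterations (|grad| = 5.3e-07)
place-field log-gain: fitted 0.696 per unit field (true 0.700)
correlation(true, fitted smooth PSF) = 0.984
post-spike gain at 3 ms: 1.84x; at one theta cycle (111 ms): 1.31x
```

The correlation of 0.984 between the true and fitted normalized smooth PSF
means the filter recovered both the immediate burst up-regulation (a 1.84×
gain 3 ms after a spike) and the theta-timescale modulation (a 1.31× gain
one 9-Hz cycle later); the place-field gain is recovered to half a percent.

The other scripts in `examples/` demonstrate session simulation and CSV
export (`01`), cross-validated place-field mapping and coherence (`02`),
feature extraction (`04`), population clustering/PCA/regression (`05`) and
the end-to-end pipeline (`06`). The pipeline is also exposed as a thin CLI:

```bash
psfglm run-all --outdir run1 --seed 3
psfglm report --outdir run1
```

## Layout

- `src/psfglm/synthetic.py` — arena, trajectories, ground-truth cells, spike emission
- `src/psfglm/maps.py` — occupancy/rate maps, CV bandwidth, coherence, firing stats
- `src/psfglm/basis.py`, `src/psfglm/glm.py` — raised-cosine basis, penalized GLM, ACGs
- `src/psfglm/features.py` — unit-power normalization and timing features
- `src/psfglm/population.py` — PCA, clustering, correlations, regression, effect sizes
- `src/psfglm/pipeline.py`, `src/psfglm/cli.py` — orchestration, session I/O, CLI
- `src/psfglm/validation.py` — the simulation-based validation studies
- `docs/methods.md` — model, assumptions, parameter choices, limitations
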