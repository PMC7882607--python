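# Methods

This note documents the models, conventions and numerical choices behind
`eegmarkers`, and what the synthetic cohorts do and do not show about real
EEG.

## Synthetic cohort model

Each channel of a trial is

```
y_c(t) = Σ_b m_{b,c} s_b(t)  +  Σ_b g_{b,c} u_{b,c}(t)  +  σ_bg · n_pink(t)  +  σ_w · n_white(t)
```

where `s_b` is one **shared** stochastic oscillator per band (theta 5 Hz,
alpha at the subject's peak, beta 20 Hz) mixed into channels through weights
`m` — this is what creates cross-channel coherence and pattern-level mutual
information — and `u_{b,c}` are channel-**independent** oscillators scaled by
gains `g`.  Oscillators are damped AR(2) resonators
`x_t = 2r cos(2πf₀/fs) x_{t−1} − r² x_{t−2} + ε_t` with
`r = exp(−π·bw/fs)`; the default bandwidth `bw = 2 Hz` gives a ~2 Hz-wide
(FWHM) spectral peak, at the narrow end of realistic alpha peaks.  Each
resonator stream discards a 500-sample burn-in and is standardized to unit
SD.  The background is 1/f^1-shaped Gaussian noise (unit SD, scale 1.0) plus
a white floor (default 0.1).

Structure in the cohort comes from three nested sources of variation:

* **Group** (the aging contrast): elderly alpha-peak mean 9 Hz vs young
  10 Hz (SD 0.5 Hz within group, a typical within-group spread), and alpha
  weights on the "occipital" block (last 25 % of channels — montage geometry
  is out of scope, channel index stands in for topography) multiplied by
  0.7.  These two effects are deliberately the *only* group differences; the
  directional literature on aging EEG motivates them, and their default
  sizes (1 Hz, 0.7) are round values of the right order.
* **Subject**: a per-subject log-normal gain pattern
  (`exp(0.4·z)` per band × channel, plus `exp(0.2·z)` jitter on the mixing
  weights) — the identity fingerprint.  0.4 makes between-subject power
  ratios of ~1.5× per channel, comparable to real test–retest EEG
  variability.
* **Condition**: the same construction with SD 0.05 — an order of magnitude
  below subject variation, so conditions of one subject stay more alike than
  different subjects (the premise behind the subject-clustering statistic).

Artifacts are injected additively with a ground-truth log (0-based half-open
sample ranges): blinks (raised-sinusoid bumps on frontal channels), muscle
bursts (120–140 Hz band-limited noise, amplitude in units of the channel
SD), jumps (steps), clips (held constant values).

What the generator does **not** emulate: volume conduction and electrode
geometry, non-stationarity within trials, eye-movement physiology,
genuine theta/beta aging effects, 50 Hz line noise.  Passing the recovery
tests therefore shows the *analysis machinery* recovers planted structure of
realistic size and noise level — not that it would rank feature sets the
same way on real recordings.

## Preprocessing conventions

Stage order is fixed: zero-phase Butterworth band-pass (order 4,
0.1–220 Hz, upper edge clamped below Nyquist) and 50 Hz IIR notch (Q = 30) →
jump/clip detection and linear interpolation → muscle-trial rejection →
common-average re-reference.  Jumps are samples whose within-trial
first-difference z-score exceeds 20 (a level shift is a spike in the
derivative); clips are maximal constant runs ≥ 0.02 s.  The muscle statistic
is the per-trial maximum of |120–140 Hz band-passed signal|, z-scored across
trials per channel with **median/MAD** (×1.4826): a mean/SD z-score is
algebraically bounded by ≈√n_trials, so at a few dozen trials several strong
bursts mask each other and can never reach the threshold; the robust form
keeps the published threshold of 5 meaningful at any trial count.  Linear
interpolation removes flagged samples but cannot undo a level shift itself;
trials with surviving broadband residue are typically caught by the muscle
stage.  Blink correction (ICA in the original chains) is a non-goal; clean
paths are produced by generating without blinks.

## Feature conventions

* Ordinal patterns: lexicographic permutation indexing (identity pattern =
  index 0), stable tie-breaking (earlier sample ranks lower — ties do occur
  in quantized EEG), windows never cross trial boundaries, histograms pooled
  over all trials of a (subject, condition) cell.  `τ_ms` resolves to
  `l = round(τ·fs/1000)` samples.
* MI in bits (base-2 logs throughout); adjacency diagonals carry the
  per-channel pattern entropy and are excluded from flattening.
* Spectra: plain untapered FFT on the common grid Δf = fs/n (an optional
  Hann taper exists, off by default); PSD = trial-mean |X|².  Band edges are
  inclusive.  Coherence is computed per bin and then averaged over the
  band's bins; a single-trial estimate is identically 1 (degenerate — use
  several trials).
* Distances: OP histograms enter d_nm as normalized distributions after
  additive smoothing ε = 1/(2·total count) per bin (the generalized KL
  diverges on empty bins; ε is half a count, configurable); PSDs enter
  unnormalized, which the generalized KL supports by construction.  The
  upper-triangle flattening is row-major over i < j.  d_nm is symmetric with
  d_nm(a,a) = 0 but is not asserted to satisfy the triangle inequality.

## Embedding

The t-SNE implementation operates on precomputed distance matrices.
Per-point Gaussian bandwidths are bisected until the row perplexity
2^H(p·|n) matches the target within 1e-5 (≤ 200 iterations); rows with
unattainable perplexity (exactly equidistant neighbors have perplexity
L−1 for every σ) return the closest achievable row rather than raising.
Joint affinities (p_m|n + p_n|m)/2 are normalized over all pairs;
low-dimensional affinities use the Student-t kernel (1+d²)^(−1).  The
optimizer is the reference recipe: 1,000 iterations, learning rate 200,
momentum 0.5→0.8 at iteration 250, ×12 early exaggeration for 250
iterations, per-coordinate adaptive gains (×0.8/+0.2, floor 0.01), seeded
Gaussian initialization (SD 1e-4).  Identical seed + input ⇒ bit-identical
output; ensembles step the seed by +1 per run.  Inputs with fewer than 4
points are rejected.  Note the plain-affinity cost can *rise* during the
early-exaggeration phase (a different objective is being descended); descent
should be judged after it ends.

## Separation statistics

Group densities are Gaussian KDEs with Scott's-rule bandwidth
(scipy's covariance-based variant, n^(−1/6)·Σ̂^(1/2) in 2-D) evaluated on one
shared 128×128 grid covering all points plus 3 bandwidths of margin; cell
masses are renormalized and compared with the base-2 Jensen–Shannon
divergence and its square root (the Jensen–Shannon distance, a metric,
bounded by 1).  Because densities are sampled at grid nodes, configurations
whose bandwidth is far below the cell size can underflow; this raises an
explicit error rather than returning spurious values.  Both divergence and
distance are reported per run, and ensembles are summarized as mean ± SD.

The permutation null shuffles group labels **across subjects**, not across
points: all conditions of one subject keep a common label.  Points of one
subject are co-located by construction, so point-level shuffles mix clusters
and systematically understate the null — with subject-level shuffles the
same statistic (the ensemble-mean distance under one permutation applied to
every run) is exchangeable with the true-label statistic under the null.

ρ divides the mean within-subject pairwise distance by the mean distance to
the points of the three nearest other subject-clusters (by centroid;
cluster membership comes from labels, not from unsupervised clustering).
The nearest-neighbor selection biases the denominator low, so the
exchangeable-data baseline sits slightly above 1 (≈1.15 for 20 subjects × 3
conditions, by direct simulation of the definition); planted subject
structure drives ρ well below 1.

## Scaled problem sizes

The study-scale defaults (45 subjects, 64 channels, 6 conditions × 80
trials, 100 t-SNE seeds, τ ∈ {15, 100} ms, four bands + full PSD) are what
`PipelineConfig()` encodes.  The recovery tests and the scaled-down profile
use 16 channels, 10+10 subjects, 3 conditions × 40 trials, perplexity 15
and 10 t-SNE seeds with a 50-permutation null — sizes at which the planted
alpha effects remain detectable for OP (τ = 15 ms) and alpha-band PSD
features while a null cohort stays inside its permutation null.  A known
limitation at this scale: the theta-band PSD feature carries group
information only through the Lorentzian tail of the shifted alpha peak past
7 Hz (no theta-specific aging effect is modeled), and its cross-group to
within-group distance ratio (~1.05) is too small for significance with 10
subjects per group; the corresponding recovery check documents this by
remaining unsatisfied at this cohort size.
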