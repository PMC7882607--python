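# eegmarkers

Ordinal-pattern and spectral biomarkers for multichannel EEG, with nonlinear
2-D embedding and statistics that quantify how well the embedded features
separate age groups and individual subjects.

## The problem

EEG studies of healthy aging consistently report two electrophysiological
effects: reduced occipital alpha power and a downward shift of the individual
alpha peak frequency in elderly subjects.  A practical question is which
*feature set* extracted from a multichannel recording best exposes such group
structure — and whether features computed from raw data can compete with
features that require a full preprocessing chain.  This package implements a
complete comparison harness for four feature families, two per domain:

| domain     | single-channel feature            | functional-connectivity feature      |
|------------|-----------------------------------|--------------------------------------|
| time       | ordinal-pattern (OP) distributions | mutual information of joint OP distributions |
| frequency  | power spectral densities (PSDs)    | trial-averaged magnitude coherence   |

Because the kind of clinical EEG cohort this targets is typically
access-restricted, the package ships a first-class **synthetic cohort
generator**: damped stochastic AR(2) resonators per frequency band (shared
sources induce connectivity; per-subject random gain patterns are identity
fingerprints) on 1/f background noise, with the two aging effects injected at
configurable sizes, plus injectable artifacts (blinks, muscle bursts, jumps,
clips) with a ground-truth event log.

## The methods

* **Ordinal patterns** (length *w*, lag *l*): each window
  *x<sub>t</sub>, x<sub>t+l</sub>, …, x<sub>t+(w−1)l</sub>* is encoded as the
  permutation sorting it ascending; there are *w*! patterns (24 for *w* = 4).
  The lag addresses a time scale τ = *l*/f<sub>s</sub>.
* **Mutual information** I(X;Y) = KL(p<sub>X,Y</sub> ‖ p<sub>X</sub>·p<sub>Y</sub>)
  in bits between joint pattern distributions of channel pairs →
  N<sub>ch</sub>×N<sub>ch</sub> adjacency matrix.
* **Coherence** coh<sub>ij</sub>(f) = |⟨X̂<sub>i</sub>X̂<sub>j</sub>*⟩| /
  √(⟨|X̂<sub>i</sub>|²⟩⟨|X̂<sub>j</sub>|²⟩) with trial-mean ⟨·⟩, averaged per
  band.
* **Distances**: single-channel feature vectors are compared with
  d<sub>nm</sub> = (1/N<sub>ch</sub>) Σ<sub>l</sub> ½[D<sub>B</sub>(S<sub>n</sub><sup>(l)</sup>‖S<sub>m</sub><sup>(l)</sup>) + D<sub>B</sub>(S<sub>m</sub><sup>(l)</sup>‖S<sub>n</sub><sup>(l)</sup>)]
  where D<sub>B</sub>(P‖Q) = Σ[p log(p/q) − p + q] is the generalized KL
  divergence (β = 1 beta-divergence); adjacency matrices are flattened
  (strict upper triangle) and compared with the Euclidean norm.
* **t-SNE**, written from first principles on precomputed distances: Gaussian
  affinities calibrated per point so the row perplexity 2^H equals a target
  *k*, Student-t low-dimensional affinities, gradient descent with momentum
  and early exaggeration on the KL cost.
* **Separation statistics**: per group, a Gaussian KDE (Scott's rule) on a
  shared grid; groups compared with the Jensen–Shannon distance
  √JSD ∈ [0,1], aggregated as mean ± SD over a seed ensemble and tested
  against a subject-level label-permutation null.  Subject clustering is
  summarized by ρ = (mean within-subject distance)/(mean distance to the
  three nearest other subject-clusters); ρ < 1 means a subject's conditions
  are projected together.

## Worked example

```bash
python examples/05_embed_and_separate.py
```

generates a 12-subject cohort with the aging effects (alpha peak 10 → 9 Hz,
occipital attenuation 0.7), computes OP-distribution features at τ = 15 ms,
embeds the 36 (subject, condition) points with a 5-seed t-SNE ensemble, and
prints:

```
distance matrix: (36, 36), metric dnm
group JSD (mean over 5 seeds): 0.855
subject-permutation null: mean 0.529, 95th pct 0.643
subject-cluster ratio ρ (mean): 0.372
```

The ensemble-mean Jensen–Shannon distance (0.855) exceeds the 95th percentile
of the subject-permutation null (0.643): the age groups genuinely separate.
ρ = 0.372 ≪ 1: each subject's three conditions land in one tight cluster.
The other examples walk through cohort synthesis, preprocessing with
artifact ground truth, ordinal and spectral features, and the end-to-end
pipeline (`run_pipeline` / the `eegmarkers` CLI), which writes a results
table with one row per feature set × parameter × raw/preprocessed path.

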