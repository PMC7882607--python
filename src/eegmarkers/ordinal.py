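"""Ordinal-pattern (Bandt–Pompe) statistics and mutual-information connectivity.

A time series is encoded window-by-window into the permutation that sorts
``w`` samples spaced ``l`` apart into ascending order; there are w! possible
patterns.  Pattern histograms per channel are the single-channel feature;
mutual information between the joint pattern distributions of channel pairs
is the time-domain functional-connectivity feature.

Conventions: permutation indices follow the lexicographic enumeration of
permutations (identity = 0); ties are broken stably, earlier samples
ranking lower; window starts advance with stride 1 and never cross trial
boundaries; mutual information and entropies are in bits (base-2 logs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import TrialSet


@dataclass
class OPConfig:
    """Pattern length ``w`` and lag ``l`` (or its time-scale alias ``tau_ms``).

    At sampling rate fs, a lag of l samples corresponds to a time scale
    τ = l / fs; e.g. τ = 15 ms at 1,000 Hz is l = 15.  A series needs at
    least (w−1)·l + 1 samples to yield one pattern.
    """

    w: int = 4
    lag: int = 1
    tau_ms: float | None = None

    def __post_init__(self) -> None:
        if self.w < 2:
            raise ValueError("pattern length w must be ≥ 2")
        if self.tau_ms is None and self.lag < 1:
            raise ValueError("lag must be ≥ 1")

    def resolve_lag(self, fs: float) -> int:
        if self.tau_ms is None:
            return self.lag
        l = int(round(self.tau_ms * fs / 1000.0))
        if l < 1:
            raise ValueError(f"tau_ms={self.tau_ms} is below one sample at fs={fs}")
        return l

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.w)

    def min_samples(self, fs: float) -> int:
        return (self.w - 1) * self.resolve_lag(fs) + 1


@dataclass
class OPDistribution:
    """Histogram (counts or probabilities) over the w! ordinal patterns."""

    counts: np.ndarray
    w: int
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (math.factorial(self.w),):
            raise ValueError(
                f"expected {math.factorial(self.w)} bins for w={self.w}, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("pattern counts must be nonnegative")
        if self.normalized and abs(self.counts.sum() - 1.0) > 1e-12:
            raise ValueError("normalized distribution must sum to 1")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalize(self) -> "OPDistribution":
        if self.normalized:
            return self
        s = self.counts.sum()
        if s == 0:
            raise ValueError("cannot normalize an empty histogram")
        return OPDistribution(self.counts / s, self.w, normalized=True, meta=dict(self.meta))

    @property
    def probabilities(self) -> np.ndarray:
        return self.normalize().counts


@dataclass
class JointOPDistribution:
    """w! × w! joint histogram over pattern pairs of two channels."""

    counts: np.ndarray
    w: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = math.factorial(self.w)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected ({k}, {k}) joint histogram, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("joint counts must be nonnegative")

    def marginal(self, axis: int) -> OPDistribution:
        return OPDistribution(self.counts.sum(axis=1 - axis), self.w)


# ----------------------------------------------------------------- encoding

_FACTORIALS = {w: np.array([math.factorial(w - 1 - i) for i in range(w)]) for w in range(2, 9)}


def encode_ordinal_patterns(series: np.ndarray, cfg: OPConfig, fs: float = 1000.0) -> np.ndarray:
    """Encode a 1-D series into its sequence of permutation indices.

    Window at start t contains samples t, t+l, …, t+(w−1)l; its pattern is
    the permutation sorting the window ascending (stable on ties) and its
    index the lexicographic rank of that permutation.  Amplitude-scale
    invariant: encode(a·x + b) = encode(x) for a > 0.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    w, l = cfg.w, cfg.resolve_lag(fs)
    span = (w - 1) * l
    if len(series) < span + 1:
        raise ValueError(
            f"series of {len(series)} samples too short for w={w}, l={l}: "
            f"need at least {span + 1} samples"
        )
    m = len(series) - span
    windows = series[np.arange(m)[:, None] + np.arange(w)[None, :] * l]
    perms = np.argsort(windows, axis=1, kind="stable")
    return _lehmer_rank(perms)


def _lehmer_rank(perms: np.ndarray) -> np.ndarray:
    """Lexicographic rank of each row-permutation (identity → 0)."""
    w = perms.shape[1]
    fact = _FACTORIALS.get(w, np.array([math.factorial(w - 1 - i) for i in range(w)]))
    idx = np.zeros(perms.shape[0], dtype=np.int64)
    for i in range(w - 1):
        smaller_later = (perms[:, i + 1:] < perms[:, i:i + 1]).sum(axis=1)
        idx += smaller_later * fact[i]
    return idx


def permutation_from_index(index: int, w: int) -> tuple[int, ...]:
    """Inverse of the lexicographic enumeration used by the encoder."""
    avail = list(range(w))
    perm = []
    for i in range(w):
        f = math.factorial(w - 1 - i)
        q, index = divmod(index, f)
        perm.append(avail.pop(q))
    return tuple(perm)


# ------------------------------------------------------------- histograms


def op_distribution(indices, w: int, normalize: bool = False, meta: dict | None = None
                    ) -> OPDistribution:
    """Pool pattern indices from one or many trials into a histogram."""
    if isinstance(indices, np.ndarray) and indices.ndim == 1:
        indices = [indices]
    arrays = [np.asarray(a, dtype=np.int64) for a in indices]
    if not arrays or sum(a.size for a in arrays) == 0:
        raise ValueError("no pattern indices to histogram")
    k = math.factorial(w)
    pooled = np.concatenate(arrays)
    if pooled.min() < 0 or pooled.max() >= k:
        raise ValueError(f"pattern index outside [0, {k}) for w={w}")
    counts = np.bincount(pooled, minlength=k).astype(float)
    dist = OPDistribution(counts, w, meta=meta or {})
    return dist.normalize() if normalize else dist


def joint_op_distribution(indices_i: np.ndarray, indices_j: np.ndarray, w: int,
                          meta: dict | None = None) -> JointOPDistribution:
    """Joint histogram over pattern pairs observed at the same window starts."""
    i = np.asarray(indices_i, dtype=np.int64)
    j = np.asarray(indices_j, dtype=np.int64)
    if i.shape != j.shape:
        raise ValueError(f"index sequences differ in length: {i.shape} vs {j.shape}")
    k = math.factorial(w)
    counts = np.bincount(i * k + j, minlength=k * k).astype(float).reshape(k, k)
    return JointOPDistribution(counts, w, meta=meta or {})


# -------------------------------------------------- information quantities


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits of a probability vector (0·log 0 := 0)."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def mutual_information(joint: JointOPDistribution) -> float:
    """MI in bits: KL divergence of the joint from the product of marginals."""
    total = joint.counts.sum()
    if total == 0:
        raise ValueError("empty joint distribution")
    p = joint.counts / total
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mask = p > 0
    assert np.all(px[mask.any(axis=1)] > 0) and np.all(py[mask.any(axis=0)] > 0)
    outer = px[:, None] * py[None, :]
    mi = float((p[mask] * np.log2(p[mask] / outer[mask])).sum())
    return max(mi, 0.0)


# ------------------------------------------------------------ connectivity


@dataclass
class AdjacencyMatrix:
    """Symmetric N_ch × N_ch functional-connectivity matrix.

    ``kind`` records the measure ("mi" in bits or "coherence" in [0, 1]);
    the diagonal convention is per-channel pattern entropy for MI and 1 for
    coherence.  The diagonal is excluded when the matrix is flattened into
    a feature vector.
    """

    values: np.ndarray
    kind: str
    channel_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("adjacency matrix must be square")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("adjacency matrix must be symmetric")
        if self.kind == "mi" and np.any(self.values < -1e-12):
            raise ValueError("MI entries must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def encode_trialset(trials: TrialSet, cfg: OPConfig) -> list[list[np.ndarray]]:
    """Pattern-index sequences per channel, one array per trial."""
    return [
        [encode_ordinal_patterns(trials.data[t, c], cfg, trials.fs)
         for t in range(trials.n_trials)]
        for c in range(trials.n_channels)
    ]


def mi_adjacency(trials: TrialSet, cfg: OPConfig) -> AdjacencyMatrix:
    """MI connectivity matrix of one (subject, condition) trial set.

    Joint pattern histograms are pooled over all trials; the diagonal holds
    each channel's pattern entropy (an upper bound on its row's MI values).
    """
    if trials.n_channels < 2:
        raise ValueError("MI adjacency needs at least 2 channels")
    idx = encode_trialset(trials, cfg)
    pooled = [np.concatenate(ch) for ch in idx]
    n_ch = trials.n_channels
    k = cfg.n_patterns
    values = np.zeros((n_ch, n_ch))
    marg = [np.bincount(p, minlength=k).astype(float) for p in pooled]
    for c in range(n_ch):
        values[c, c] = shannon_entropy(marg[c] / marg[c].sum())
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            joint = joint_op_distribution(pooled[i], pooled[j], cfg.w)
            values[i, j] = values[j, i] = mutual_information(joint)
    return AdjacencyMatrix(
        values, kind="mi", channel_names=list(trials.channel_names),
        meta={"subject": trials.subject, "group": trials.group,
              "condition": trials.condition, "w": cfg.w,
              "lag": cfg.resolve_lag(trials.fs)},
    )
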