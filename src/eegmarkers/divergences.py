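"""Distances between feature objects.

Three distance routes feed the embedding:

* the generalized Kullback–Leibler divergence
  D_B(P‖Q) = Σ [p log(p/q) − p + q] between nonnegative, not necessarily
  normalized vectors (the β = 1 member of the beta-divergence family);
* d_nm, its channel-averaged symmetrized form between two vectors of
  per-channel distributions (ordinal-pattern histograms or PSDs);
* plain Euclidean distance between flattened strict upper triangles of
  connectivity matrices.

The Jensen–Shannon divergence between normalized densities (base-2 logs,
bounded by 1; its square root is a metric) lives here too — it is what the
separation statistics compare group densities with.

Empirical pattern histograms can have empty bins, on which D_B diverges;
before comparison each histogram receives additive smoothing of
ε = 1/(2·total count) per bin (configurable) and is renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .ordinal import AdjacencyMatrix, OPDistribution
from .spectral import PSDSet


@dataclass
class ChannelFeatureVector:
    """One sample point: N_ch nonnegative distributions on a shared support."""

    distributions: np.ndarray  # (n_channels, n_bins)
    kind: str  # "op_dist" | "psd"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distributions = np.asarray(self.distributions, dtype=float)
        if self.distributions.ndim != 2 or self.distributions.shape[0] < 1:
            raise ValueError("need a (n_channels, n_bins) array with n_channels ≥ 1")
        if np.any(self.distributions < 0):
            raise ValueError("distributions must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.distributions.shape[0]

    @classmethod
    def from_op_distributions(cls, dists: list[OPDistribution], smooth: bool = True,
                              meta: dict | None = None) -> "ChannelFeatureVector":
        """Stack per-channel pattern histograms as normalized distributions.

        With ``smooth`` (default), ε = 1/(2·total) is added to every bin of a
        channel's histogram before normalizing, so later divergences stay
        finite on unobserved patterns.
        """
        rows = []
        for d in dists:
            c = d.counts.astype(float)
            if smooth:
                total = c.sum()
                if total == 0:
                    raise ValueError("cannot smooth an empty histogram")
                c = c + 1.0 / (2.0 * total)
            rows.append(c / c.sum())
        return cls(np.stack(rows), kind="op_dist", meta=meta or {})

    @classmethod
    def from_psd(cls, psd: PSDSet, normalize: bool = False,
                 meta: dict | None = None) -> "ChannelFeatureVector":
        """Wrap a PSD set; unnormalized by default (D_B handles raw densities)."""
        rows = psd.psd.astype(float)
        if normalize:
            rows = rows / rows.sum(axis=1, keepdims=True)
        m = dict(psd.meta)
        m.update(meta or {})
        if psd.band is not None:
            m.setdefault("band", psd.band.name)
        return cls(rows, kind="psd", meta=m)


@dataclass
class DistanceMatrix:
    """L × L symmetric nonnegative distances between sample points."""

    values: np.ndarray
    kind: str  # "dnm" | "euclidean-upper-triangular"
    labels: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if np.max(np.abs(self.values - self.values.T)) > 1e-9:
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def __len__(self) -> int:
        return self.values.shape[0]


# --------------------------------------------------------------- divergences


def generalized_kl(P: np.ndarray, Q: np.ndarray) -> float:
    """D_B(P‖Q) = Σ [p log(p/q) − p + q] over a shared support (natural log).

    Defined for nonnegative, not necessarily normalized vectors; zero iff
    P = Q, with 0·log 0 := 0.  Raises if some bin has p > 0 but q = 0.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"support mismatch: {P.shape} vs {Q.shape}")
    if np.any(P < 0) or np.any(Q < 0):
        raise ValueError("inputs must be nonnegative")
    bad = (P > 0) & (Q == 0)
    if bad.any():
        raise ValueError(f"q = 0 with p > 0 at bin {int(np.argmax(bad))}: divergence infinite")
    mask = P > 0
    val = float((P[mask] * np.log(P[mask] / Q[mask])).sum() - P.sum() + Q.sum())
    return max(val, 0.0)


def dnm_distance(a: ChannelFeatureVector, b: ChannelFeatureVector) -> float:
    """Channel-averaged symmetrized generalized KL between two feature vectors.

    d = (1/N_ch) Σ_l ½ [D_B(S_a(l)‖S_b(l)) + D_B(S_b(l)‖S_a(l))]; symmetric
    and zero iff all channel distributions agree.
    """
    if a.n_channels != b.n_channels:
        raise ValueError(f"channel-count mismatch: {a.n_channels} vs {b.n_channels}")
    if a.distributions.shape != b.distributions.shape:
        raise ValueError("feature vectors must share one support")
    acc = 0.0
    for l in range(a.n_channels):
        p, q = a.distributions[l], b.distributions[l]
        acc += 0.5 * (generalized_kl(p, q) + generalized_kl(q, p))
    return acc / a.n_channels


def flatten_upper(adj: AdjacencyMatrix, tol: float = 1e-9) -> np.ndarray:
    """Strict upper triangle in row-major (i<j) order — N(N−1)/2 entries."""
    v = adj.values
    if np.max(np.abs(v - v.T)) > tol:
        raise ValueError("matrix asymmetric beyond tolerance")
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu].copy()


def unflatten_upper(vec: np.ndarray, n: int) -> np.ndarray:
    """Rebuild the symmetric matrix (zero diagonal) from its flattened triangle."""
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    return out + out.T


def pairwise_distances(samples: list, labels: list[dict] | None = None) -> DistanceMatrix:
    """Full distance matrix over homogeneous samples.

    ``ChannelFeatureVector`` samples are compared with d_nm; adjacency
    matrices are flattened (strict upper triangle) and compared with the
    Euclidean norm.  Mixed sample kinds are rejected.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    kinds = {type(s).__name__ for s in samples}
    if len(kinds) > 1:
        raise ValueError(f"mixed sample kinds: {kinds}")
    labels = labels if labels is not None else [getattr(s, "meta", {}) for s in samples]
    if isinstance(samples[0], ChannelFeatureVector):
        feature_kinds = {s.kind for s in samples}
        if len(feature_kinds) > 1:
            raise ValueError(f"mixed feature kinds: {feature_kinds}")
        L = len(samples)
        values = np.zeros((L, L))
        for i in range(L):
            for j in range(i + 1, L):
                values[i, j] = values[j, i] = dnm_distance(samples[i], samples[j])
        return DistanceMatrix(values, kind="dnm", labels=labels)
    if isinstance(samples[0], AdjacencyMatrix):
        flat = np.stack([flatten_upper(a) for a in samples])
        values = squareform(pdist(flat, metric="euclidean"))
        return DistanceMatrix(values, kind="euclidean-upper-triangular", labels=labels)
    raise TypeError(f"unsupported sample type {type(samples[0]).__name__}")


def jensen_shannon(P: np.ndarray, Q: np.ndarray, base: float = 2.0) -> tuple[float, float]:
    """Jensen–Shannon divergence and distance between normalized densities.

    JSD(P‖Q) = ½ KL(P‖M) + ½ KL(Q‖M) with M = (P+Q)/2; bounded by 1 for
    base-2 logs, attained on disjoint supports.  Returns (divergence,
    distance = sqrt(divergence)).
    """
    P = np.asarray(P, dtype=float).ravel()
    Q = np.asarray(Q, dtype=float).ravel()
    if P.shape != Q.shape:
        raise ValueError("densities must share one grid")
    if np.any(P < 0) or np.any(Q < 0):
        raise ValueError("densities must be nonnegative")
    sp, sq = P.sum(), Q.sum()
    if sp <= 0 or sq <= 0:
        raise ValueError("cannot normalize a zero density")
    if abs(sp - 1) > 1e-6:
        P = P / sp
    if abs(sq - 1) > 1e-6:
        Q = Q / sq
    M = 0.5 * (P + Q)
    log = np.log2 if base == 2.0 else (lambda x: np.log(x) / np.log(base))

    def _kl(p, m):
        mask = p > 0
        return float((p[mask] * log(p[mask] / m[mask])).sum())

    div = 0.5 * _kl(P, M) + 0.5 * _kl(Q, M)
    div = float(np.clip(div, 0.0, 1.0 if base == 2.0 else np.inf))
    return div, float(np.sqrt(div))
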