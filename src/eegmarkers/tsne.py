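"""t-distributed stochastic neighbor embedding on precomputed distances.

Written from first principles for full control of the affinity conventions:
Gaussian conditional affinities p_m|n with per-point bandwidths σ_n
calibrated by bisection so the row perplexity 2^H(p_·|n) matches a target k;
symmetrized joint affinities p_nm = (p_m|n + p_n|m)/2 normalized over all
pairs; Student-t low-dimensional affinities q_nm ∝ (1 + ‖y_n − y_m‖²)^(−1);
and gradient descent with momentum and early exaggeration on the KL cost
C = Σ_{n≠m} p_nm log(p_nm / q_nm).

Everything is deterministic given the seed; ensembles simply step the seed.
No Barnes–Hut style acceleration — cohort-scale inputs are a few hundred
points at most.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .divergences import DistanceMatrix

_EPS = 1e-12


@dataclass
class TSNEConfig:
    """Optimizer and calibration settings.

    Defaults are the widely used reference settings: 1,000 iterations at
    learning rate 200, momentum 0.5 switching to 0.8 at iteration 250, and
    ×12 early exaggeration for the first 250 iterations.
    """

    perplexity: float = 30.0
    n_components: int = 2
    n_iter: int = 1000
    learning_rate: float = 200.0
    momentum_init: float = 0.5
    momentum_final: float = 0.8
    momentum_switch: int = 250
    early_exaggeration: float = 12.0
    ee_iter: int = 250
    init_sd: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components not in (2, 3):
            raise ValueError("output dimension must be 2 or 3")


@dataclass
class Embedding2D:
    """Projected coordinates with their labels and final cost."""

    Y: np.ndarray  # (L, M)
    labels: list[dict] = field(default_factory=list)
    cost: float = np.nan
    seed: int = 0

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("embedding coordinates must be finite")
        if self.labels and len(self.labels) != self.Y.shape[0]:
            raise ValueError("one label per point required")


# ----------------------------------------------------------------- affinities


def conditional_affinities(D: DistanceMatrix | np.ndarray, perplexity: float,
                           tol: float = 1e-5, max_iter: int = 200
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic Gaussian affinities calibrated to a perplexity.

    Row n: p_m|n ∝ exp(−d(n,m)² / (2σ_n²)) with p_n|n = 0; σ_n is found by
    bisection on the precision so that 2^H(p_·|n) = perplexity within
    ``tol``.  Returns (P, sigmas).  On rows where the perplexity is not
    attainable (e.g. exactly equidistant neighbors, whose perplexity is
    L−1 for every σ) the closest achievable row is returned.
    """
    values = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    L = values.shape[0]
    if not 1 < perplexity < L - 1 + 1e-9:
        raise ValueError(f"perplexity must lie in (1, L−1) = (1, {L - 1}), got {perplexity}")
    D2 = values ** 2
    P = np.zeros((L, L))
    sigmas = np.empty(L)
    target = np.log2(perplexity)
    for n in range(L):
        d2 = np.delete(D2[n], n)
        beta_lo, beta_hi = 0.0, np.inf
        beta = 1.0
        row = None
        for _ in range(max_iter):
            row, H = _row_entropy(d2, beta)
            diff = H - target
            if abs(diff) < tol:
                break
            if diff > 0:  # too flat → narrow the kernel
                beta_lo = beta
                beta = beta * 2 if beta_hi == np.inf else 0.5 * (beta + beta_hi)
            else:
                beta_hi = beta
                beta = beta / 2 if beta_lo == 0.0 else 0.5 * (beta + beta_lo)
        if row is None or not np.all(np.isfinite(row)):
            raise RuntimeError(
                f"perplexity calibration failed on row {n}: beta={beta}, "
                f"distances in [{d2.min()}, {d2.max()}]"
            )
        P[n] = np.insert(row, n, 0.0)
        sigmas[n] = np.sqrt(0.5 / beta)
    return P, sigmas


def _row_entropy(d2: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    logits = -d2 * beta
    logits -= logits.max()
    p = np.exp(logits)
    s = p.sum()
    p /= s
    nz = p[p > 0]
    H = float(-(nz * np.log2(nz)).sum())
    return p, H


def symmetrize(P_cond: np.ndarray) -> np.ndarray:
    """Joint affinities p_nm = (p_m|n + p_n|m)/2, normalized over all pairs."""
    S = P_cond + P_cond.T
    return S / S.sum()


def low_dim_affinities(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Student-t affinities q_nm and the unnormalized kernel w_nm = (1+d²)^(−1)."""
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("coordinates must be finite")
    W = 1.0 / (1.0 + squareform(pdist(Y, "sqeuclidean")))
    np.fill_diagonal(W, 0.0)
    Q = W / W.sum()
    return Q, W


# ----------------------------------------------------------------- optimizer


def tsne_cost(P: np.ndarray, Y: np.ndarray) -> float:
    """KL cost C = Σ_{n≠m} p_nm log(p_nm / q_nm)."""
    Q, _ = low_dim_affinities(Y)
    mask = P > 0
    return float((P[mask] * np.log(P[mask] / np.maximum(Q[mask], _EPS))).sum())


def tsne_gradient(P: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Analytic gradient dC/dY = 4 Σ_m (p_nm − q_nm) w_nm (y_n − y_m)."""
    Q, W = low_dim_affinities(Y)
    G = (P - Q) * W
    return 4.0 * (G.sum(axis=1)[:, None] * Y - G @ Y)


def tsne(D: DistanceMatrix, cfg: TSNEConfig | None = None) -> Embedding2D:
    """Embed a distance matrix by gradient descent on the KL cost.

    Seeded isotropic Gaussian initialization (SD ``init_sd``); identical
    seed and input give bit-identical output.
    """
    cfg = cfg or TSNEConfig()
    L = len(D)
    if L < 4:
        raise ValueError(f"need at least 4 points to embed, got {L}")
    P_cond, _ = conditional_affinities(D, cfg.perplexity)
    P = np.maximum(symmetrize(P_cond), _EPS)

    rng = np.random.default_rng(abs(cfg.seed))
    Y = cfg.init_sd * rng.standard_normal((L, cfg.n_components))
    update = np.zeros_like(Y)
    gains = np.ones_like(Y)  # per-coordinate adaptive step sizes
    for it in range(cfg.n_iter):
        target = P * cfg.early_exaggeration if it < cfg.ee_iter else P
        grad = tsne_gradient(target, Y)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite gradient at iteration {it}")
        momentum = cfg.momentum_init if it < cfg.momentum_switch else cfg.momentum_final
        same_sign = np.sign(grad) == np.sign(update)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        np.clip(gains, 0.01, None, out=gains)
        update = momentum * update - cfg.learning_rate * gains * grad
        Y = Y + update
        Y = Y - Y.mean(axis=0)
    cost = tsne_cost(P, Y)
    if not np.isfinite(cost):
        raise FloatingPointError(f"non-finite cost after {cfg.n_iter} iterations")
    return Embedding2D(Y=Y, labels=list(D.labels), cost=cost, seed=cfg.seed)


def tsne_ensemble(D: DistanceMatrix, cfg: TSNEConfig | None = None,
                  n_runs: int = 100) -> list[Embedding2D]:
    """Repeat the embedding with seeds seed+0 … seed+n_runs−1."""
    cfg = cfg or TSNEConfig()
    if n_runs < 1:
        raise ValueError("n_runs must be ≥ 1")
    out = []
    for r in range(n_runs):
        run_cfg = TSNEConfig(**{**cfg.__dict__, "seed": cfg.seed + r})
        try:
            out.append(tsne(D, run_cfg))
        except Exception as e:
            raise RuntimeError(f"t-SNE run {r} (seed {cfg.seed + r}) failed") from e
    return out
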