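"""Group-separation and subject-clustering statistics on 2-D embeddings.

Age-group separation: a Gaussian kernel density estimate (Scott's rule
bandwidth) per group on one shared evaluation grid, compared with the
Jensen–Shannon divergence (base-2, bounded by 1) and its square root, the
Jensen–Shannon distance.  Aggregated as mean ± SD over an ensemble of
embeddings with different seeds.

Subject clustering: the ratio ρ between the average pairwise distance
within a subject's points and the average distance from those points to the
points of the three nearest other subject-clusters (by centroid).  ρ ≪ 1
means a subject's conditions are projected together; ρ ≈ 1 means subjects
are exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .divergences import jensen_shannon
from .tsne import Embedding2D


@dataclass
class SeparationResult:
    """Ensemble summary of per-run separation values."""

    per_run_distance: np.ndarray  # sqrt-JSD per run, in [0, 1]
    per_run_divergence: np.ndarray  # raw JSD per run, in [0, 1]
    mean: float = 0.0
    sd: float = 0.0
    divergence_mean: float = 0.0
    divergence_sd: float = 0.0
    rho_per_subject: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.per_run_distance, dtype=float)
        if np.any((d < 0) | (d > 1)):
            raise ValueError("per-run JSD values must lie in [0, 1]")
        self.mean = float(d.mean())
        self.sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
        v = np.asarray(self.per_run_divergence, dtype=float)
        self.divergence_mean = float(v.mean())
        self.divergence_sd = float(v.std(ddof=1)) if v.size > 1 else 0.0


# ------------------------------------------------------------------- KDE


def _scott_bandwidths(points: np.ndarray) -> np.ndarray:
    """Per-dimension Scott's-rule bandwidths: n^(−1/(d+4)) × data SD."""
    n, d = points.shape
    return points.std(axis=0, ddof=1) * n ** (-1.0 / (d + 4))


def kde_2d(points: np.ndarray, grid_x: np.ndarray, grid_y: np.ndarray) -> np.ndarray:
    """Gaussian-kernel density (Scott's rule) as cell masses on a grid.

    Returns an array of shape (len(grid_x), len(grid_y)) whose entries are
    the density evaluated at the cell nodes times the cell area, renormalized
    to sum to 1.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if points.shape[0] < 3:
        raise ValueError("KDE needs at least 3 points")
    if np.any(points.std(axis=0) == 0):
        raise ValueError("degenerate (zero-variance) coordinates")
    try:
        kde = gaussian_kde(points.T, bw_method="scott")
    except np.linalg.LinAlgError as e:
        raise ValueError("degenerate point configuration for KDE") from e
    XX, YY = np.meshgrid(grid_x, grid_y, indexing="ij")
    dens = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
    mass = dens * (grid_x[1] - grid_x[0]) * (grid_y[1] - grid_y[0])
    s = mass.sum()
    if s <= 0:
        raise ValueError("KDE mass vanished on the evaluation grid")
    return mass / s


def evaluation_grid(points: np.ndarray, gridsize: int = 128,
                    margin_bandwidths: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular grid covering the points plus a few bandwidths of margin."""
    points = np.asarray(points, dtype=float)
    bw = _scott_bandwidths(points)
    lo = points.min(axis=0) - margin_bandwidths * bw
    hi = points.max(axis=0) + margin_bandwidths * bw
    return np.linspace(lo[0], hi[0], gridsize), np.linspace(lo[1], hi[1], gridsize)


# ----------------------------------------------------------- group separation


def group_jsd(embedding: Embedding2D, group_key: str = "group",
              gridsize: int = 128) -> tuple[float, float]:
    """Jensen–Shannon (divergence, distance) between the two groups' KDEs.

    Both densities are estimated on one shared grid built from all points,
    so the statistic is invariant under rigid motions of the embedding.
    """
    groups = _split_groups(embedding, group_key)
    gx, gy = evaluation_grid(embedding.Y, gridsize=gridsize)
    masses = [kde_2d(pts, gx, gy) for pts in groups.values()]
    return jensen_shannon(masses[0], masses[1], base=2.0)


def _split_groups(embedding: Embedding2D, group_key: str) -> dict[str, np.ndarray]:
    labels = [lab.get(group_key) for lab in embedding.labels]
    names = list(dict.fromkeys(labels))
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, found {names}")
    out = {}
    for name in names:
        pts = embedding.Y[np.array([lab == name for lab in labels])]
        if pts.shape[0] < 3:
            raise ValueError(f"group {name!r} has fewer than 3 points")
        out[name] = pts
    return out


def ensemble_jsd(embeddings: list[Embedding2D], group_key: str = "group",
                 gridsize: int = 128, meta: dict | None = None) -> SeparationResult:
    """Mean and SD of the per-run group JSD over a seed ensemble."""
    if len(embeddings) < 2:
        raise ValueError("need at least 2 runs to summarize an ensemble")
    divs, dists = [], []
    for emb in embeddings:
        div, dist = group_jsd(emb, group_key=group_key, gridsize=gridsize)
        divs.append(div)
        dists.append(dist)
    return SeparationResult(
        per_run_distance=np.array(dists), per_run_divergence=np.array(divs),
        meta=meta or {},
    )


def _subject_permutations(labels: list[dict], n_shuffles: int, seed: int,
                          group_key: str, subject_key: str) -> list[dict[str, str]]:
    """Random reassignments of group labels across subjects (sizes preserved).

    The exchangeable unit under the no-group-difference null is the subject,
    not the point: all of a subject's conditions carry one group label and
    are projected close together, so point-level shuffles would produce a
    null that is too easy to beat.
    """
    rng = np.random.default_rng(abs(seed))
    subj_group = {}
    for lab in labels:
        subj_group.setdefault(lab[subject_key], lab[group_key])
    subjects = list(subj_group)
    groups = list(subj_group.values())
    maps = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(subjects))
        maps.append({s: groups[p] for s, p in zip(subjects, perm)})
    return maps


def _relabel(embedding: Embedding2D, mapping: dict[str, str],
             group_key: str, subject_key: str) -> Embedding2D:
    labels = [dict(lab, **{group_key: mapping[lab[subject_key]]})
              for lab in embedding.labels]
    return Embedding2D(Y=embedding.Y, labels=labels, cost=embedding.cost,
                       seed=embedding.seed)


def shuffled_label_jsd(embedding: Embedding2D, n_shuffles: int, seed: int,
                       group_key: str = "group", subject_key: str = "subject",
                       gridsize: int = 128) -> np.ndarray:
    """Null distribution of the JSD distance under subject-level group shuffles."""
    maps = _subject_permutations(embedding.labels, n_shuffles, seed,
                                 group_key, subject_key)
    return np.array([
        group_jsd(_relabel(embedding, m, group_key, subject_key),
                  group_key=group_key, gridsize=gridsize)[1]
        for m in maps
    ])


def ensemble_shuffled_jsd(embeddings: list[Embedding2D], n_shuffles: int, seed: int,
                          group_key: str = "group", subject_key: str = "subject",
                          gridsize: int = 128) -> np.ndarray:
    """Permutation null of the ensemble-mean JSD distance.

    Each shuffle draws one subject-level group relabeling and applies it to
    every embedding in the ensemble, returning the mean JSD across runs —
    the same statistic the true labels are summarized by, so comparing the
    true ensemble mean against this distribution is a permutation test of
    the ensemble-level statistic.
    """
    maps = _subject_permutations(embeddings[0].labels, n_shuffles, seed,
                                 group_key, subject_key)
    means = np.empty(n_shuffles)
    for s, m in enumerate(maps):
        means[s] = float(np.mean([
            group_jsd(_relabel(emb, m, group_key, subject_key),
                      group_key=group_key, gridsize=gridsize)[1]
            for emb in embeddings
        ]))
    return means


# --------------------------------------------------------- subject clustering


def cluster_ratio_rho(embedding: Embedding2D, n_neighbors: int = 3,
                      subject_key: str = "subject") -> dict[str, float]:
    """Within-subject vs nearest-neighbor-cluster distance ratio per subject.

    numerator: mean pairwise distance among the subject's points;
    denominator: mean distance from the subject's points to all points of
    the ``n_neighbors`` other subjects with nearest centroids.
    """
    subjects: dict[str, np.ndarray] = {}
    labels = [lab.get(subject_key) for lab in embedding.labels]
    for name in dict.fromkeys(labels):
        pts = embedding.Y[np.array([lab == name for lab in labels])]
        if pts.shape[0] < 2:
            raise ValueError(f"subject {name!r} has fewer than 2 points")
        subjects[name] = pts
    if len(subjects) < n_neighbors + 1:
        raise ValueError(f"need at least {n_neighbors + 1} subjects, got {len(subjects)}")
    centroids = {s: pts.mean(axis=0) for s, pts in subjects.items()}
    rho: dict[str, float] = {}
    for s, pts in subjects.items():
        diffs = pts[:, None, :] - pts[None, :, :]
        dists = np.sqrt((diffs ** 2).sum(-1))
        iu = np.triu_indices(len(pts), k=1)
        within = float(dists[iu].mean())
        others = sorted(
            (np.linalg.norm(centroids[o] - centroids[s]), o)
            for o in subjects if o != s
        )[:n_neighbors]
        neigh_pts = np.vstack([subjects[o] for _, o in others])
        cross = np.sqrt(((pts[:, None, :] - neigh_pts[None, :, :]) ** 2).sum(-1))
        rho[s] = within / float(cross.mean())
    return rho
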