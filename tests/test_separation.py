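"""KDE-based group separation and subject-cluster ratio."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from eegmarkers import (
    Embedding2D,
    cluster_ratio_rho,
    ensemble_jsd,
    group_jsd,
    kde_2d,
    shuffled_label_jsd,
)
from eegmarkers.separation import evaluation_grid


def make_embedding(points, groups, subjects=None):
    subjects = subjects or [f"S{i}" for i in range(len(points))]
    labels = [{"subject": s, "group": g} for s, g in zip(subjects, groups)]
    return Embedding2D(Y=np.asarray(points, dtype=float), labels=labels)


# ----------------------------------------------------------------------- KDE


def test_kde_normalized_nonnegative_and_mode_near_centroid(rng):
    pts = rng.normal([3.0, -2.0], 0.1, size=(40, 2))
    gx, gy = evaluation_grid(pts)
    mass = kde_2d(pts, gx, gy)
    assert np.all(mass >= 0)
    assert mass.sum() == pytest.approx(1.0, abs=1e-6)
    # on a wide grid the tight cluster's mode falls within one cell of its centroid
    gx = gy = np.linspace(-10, 10, 64)
    mass = kde_2d(pts, gx, gy)
    i, j = np.unravel_index(np.argmax(mass), mass.shape)
    cell = gx[1] - gx[0]
    assert abs(gx[i] - 3.0) <= cell and abs(gy[j] - (-2.0)) <= cell


def test_kde_matches_analytic_gaussian_at_large_n(rng):
    pts = rng.standard_normal((4000, 2))
    gx, gy = evaluation_grid(pts)
    est = kde_2d(pts, gx, gy)
    XX, YY = np.meshgrid(gx, gy, indexing="ij")
    exact = multivariate_normal([0, 0], np.eye(2)).pdf(np.dstack([XX, YY]))
    exact = exact * (gx[1] - gx[0]) * (gy[1] - gy[0])
    exact /= exact.sum()
    # total variation between estimated and analytic cell masses
    assert 0.5 * np.abs(est - exact).sum() < 0.1


def test_kde_rejects_degenerate_inputs(rng):
    gx = gy = np.linspace(-1, 1, 32)
    with pytest.raises(ValueError, match="at least 3"):
        kde_2d(np.zeros((2, 2)), gx, gy)
    with pytest.raises(ValueError, match="degenerate"):
        kde_2d(np.tile([1.0, 2.0], (10, 1)), gx, gy)


# ----------------------------------------------------------- group separation


def test_group_jsd_identical_far_apart_and_shuffled(rng):
    pts = rng.standard_normal((20, 2))
    both = np.vstack([pts, pts])
    emb = make_embedding(both, ["young"] * 20 + ["elderly"] * 20,
                         subjects=[f"S{i}" for i in range(20)] * 2)
    div, dist = group_jsd(emb)
    assert div == pytest.approx(0.0, abs=1e-9)
    # groups far apart with small spread: divergence saturates at the bound
    far = np.vstack([rng.normal(0, 1.0, (20, 2)), rng.normal(200, 1.0, (20, 2))])
    emb = make_embedding(far, ["young"] * 20 + ["elderly"] * 20)
    div, dist = group_jsd(emb)
    assert div == pytest.approx(1.0, abs=1e-6)
    assert dist == pytest.approx(1.0, abs=1e-6)
    # subject-level label shuffles destroy the separation
    null = shuffled_label_jsd(emb, n_shuffles=20, seed=5)
    assert np.all(null < dist)


def test_group_jsd_invariant_under_rigid_motion(rng):
    pts = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(3, 1, (15, 2))])
    groups = ["young"] * 15 + ["elderly"] * 15
    emb = make_embedding(pts, groups)
    shifted = make_embedding(pts + np.array([100.0, -40.0]), groups)
    assert group_jsd(shifted)[1] == pytest.approx(group_jsd(emb)[1], abs=1e-7)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    rotated = make_embedding(pts @ R.T, groups)
    # rotation is exact for the kernel but re-grids the axis-aligned cells
    assert group_jsd(rotated)[1] == pytest.approx(group_jsd(emb)[1], abs=0.01)


def test_group_jsd_requires_two_groups(rng):
    emb = make_embedding(rng.standard_normal((10, 2)), ["young"] * 10)
    with pytest.raises(ValueError, match="2 groups"):
        group_jsd(emb)


def test_ensemble_jsd_summary_and_order_invariance(rng):
    pts = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(5, 1, (10, 2))])
    groups = ["young"] * 10 + ["elderly"] * 10
    embs = [make_embedding(pts, groups) for _ in range(4)]
    res = ensemble_jsd(embs)
    assert res.sd == 0.0  # identical runs
    assert res.mean == pytest.approx(group_jsd(embs[0])[1])
    res_rev = ensemble_jsd(embs[::-1])
    assert res_rev.mean == res.mean
    with pytest.raises(ValueError, match="2 runs"):
        ensemble_jsd(embs[:1])


# --------------------------------------------------------- subject clustering


def rho_brute_force(points, subjects, n_neighbors=3):
    """Oracle: explicit double loops over points and clusters."""
    names = list(dict.fromkeys(subjects))
    idx = {s: [i for i, x in enumerate(subjects) if x == s] for s in names}
    cents = {s: np.mean([points[i] for i in idx[s]], axis=0) for s in names}
    out = {}
    for s in names:
        pts = idx[s]
        within, cnt = 0.0, 0
        for i in pts:
            for j in pts:
                if i < j:
                    within += np.linalg.norm(points[i] - points[j])
                    cnt += 1
        within /= cnt
        ranked = sorted((np.linalg.norm(cents[o] - cents[s]), o)
                        for o in names if o != s)[:n_neighbors]
        cross, cnt = 0.0, 0
        for _, o in ranked:
            for i in pts:
                for j in idx[o]:
                    cross += np.linalg.norm(points[i] - points[j])
                    cnt += 1
        out[s] = within / (cross / cnt)
    return out


def test_rho_matches_brute_force_oracle(rng):
    points = rng.standard_normal((15, 2))
    subjects = [f"S{i // 3}" for i in range(15)]  # 5 subjects × 3 points
    emb = make_embedding(points, ["g"] * 15, subjects=subjects)
    rho = cluster_ratio_rho(emb)
    oracle = rho_brute_force(points, subjects)
    for s in oracle:
        assert rho[s] == pytest.approx(oracle[s], abs=1e-12)


def test_rho_small_for_tight_separated_blobs(rng):
    centers = rng.uniform(-50, 50, (8, 2))
    points = np.vstack([c + 0.1 * rng.standard_normal((3, 2)) for c in centers])
    subjects = [f"S{i // 3}" for i in range(24)]
    emb = make_embedding(points, ["g"] * 24, subjects=subjects)
    rho = cluster_ratio_rho(emb)
    assert all(v < 0.1 for v in rho.values())


def test_rho_near_one_for_exchangeable_points(rng):
    """Points drawn from one distribution regardless of subject: ρ ≈ 1.

    The nearest-3-cluster denominator is slightly biased low, so the
    exchangeable baseline sits a little above 1 (≈1.15 for 20 subjects of 3
    points; frozen from an independent simulation of the definition).
    """
    means = []
    for _ in range(20):
        points = rng.standard_normal((60, 2))
        subjects = [f"S{i // 3}" for i in range(60)]
        emb = make_embedding(points, ["g"] * 60, subjects=subjects)
        means.append(np.mean(list(cluster_ratio_rho(emb).values())))
    assert np.mean(means) == pytest.approx(1.15, abs=0.1)


def test_rho_requires_enough_subjects(rng):
    emb = make_embedding(rng.standard_normal((6, 2)), ["g"] * 6,
                         subjects=["A", "A", "B", "B", "C", "C"])
    with pytest.raises(ValueError, match="at least 4 subjects"):
        cluster_ratio_rho(emb)
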