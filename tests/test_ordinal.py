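"""Ordinal-pattern encoding, histograms, and mutual information."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from eegmarkers import (
    OPConfig,
    encode_ordinal_patterns,
    joint_op_distribution,
    mi_adjacency,
    mutual_information,
    op_distribution,
)
from eegmarkers.datasets import TrialSet
from eegmarkers.ordinal import JointOPDistribution, permutation_from_index, shannon_entropy


def brute_force_encode(series, w, l):
    """Oracle: explicit lexicographic rank of each window's sorting permutation."""
    perms = list(itertools.permutations(range(w)))  # lexicographic order
    out = []
    for t in range(len(series) - (w - 1) * l):
        window = [series[t + i * l] for i in range(w)]
        order = sorted(range(w), key=lambda i: (window[i], i))  # stable
        out.append(perms.index(tuple(order)))
    return np.array(out)


@pytest.mark.parametrize("w,l", [(2, 1), (3, 1), (3, 2), (4, 1), (4, 3)])
def test_monotone_series_maps_to_identity_pattern(w, l):
    idx = encode_ordinal_patterns(np.arange(100.0), OPConfig(w=w, lag=l))
    assert np.all(idx == 0)
    assert len(idx) == 100 - (w - 1) * l


def test_all_24_patterns_realized_for_w4():
    """Exhaustively permuted 4-point windows hit each of the 24 indices once."""
    seen = set()
    for perm in itertools.permutations(range(4)):
        idx = encode_ordinal_patterns(np.array(perm, dtype=float), OPConfig(w=4))
        assert idx.shape == (1,)
        seen.add(int(idx[0]))
    assert seen == set(range(24))


@pytest.mark.parametrize("w,l", [(3, 2), (4, 1), (4, 5)])
def test_encoding_matches_brute_force_oracle(rng, w, l):
    x = rng.standard_normal(50 + (w - 1) * l)
    assert np.array_equal(encode_ordinal_patterns(x, OPConfig(w=w, lag=l)),
                          brute_force_encode(x, w, l))


def test_encoding_is_amplitude_scale_invariant(rng):
    x = rng.standard_normal(200)
    ref = encode_ordinal_patterns(x, OPConfig(w=4, lag=2))
    for a, b in [(2.5, 0.0), (0.1, -7.0), (1e6, 3.0)]:
        assert np.array_equal(encode_ordinal_patterns(a * x + b, OPConfig(w=4, lag=2)), ref)


def test_ties_broken_stably_earlier_sample_ranks_lower():
    # constant window: stable argsort is the identity permutation
    idx = encode_ordinal_patterns(np.zeros(10), OPConfig(w=3))
    assert np.all(idx == 0)


def test_tau_ms_lag_semantics():
    assert OPConfig(w=4, tau_ms=15.0).resolve_lag(1000.0) == 15
    assert OPConfig(w=4, tau_ms=100.0).resolve_lag(1000.0) == 100
    assert OPConfig(w=4, tau_ms=100.0).min_samples(1000.0) == 301


def test_too_short_series_raises_with_minimum_length():
    with pytest.raises(ValueError, match="at least 31"):
        encode_ordinal_patterns(np.zeros(30), OPConfig(w=4, lag=10))


def test_permutation_index_round_trip():
    for w in (3, 4):
        for k in range(math.factorial(w)):
            perm = permutation_from_index(k, w)
            window = np.empty(w)
            window[list(perm)] = np.arange(w)  # realizes exactly this pattern
            assert int(encode_ordinal_patterns(window, OPConfig(w=w))[0]) == k


# --------------------------------------------------------------- histograms


def test_op_distribution_point_mass_and_additivity(rng):
    d = op_distribution(np.zeros(10, dtype=int), w=3)
    assert d.counts[0] == 10 and d.counts[1:].sum() == 0
    a = rng.integers(0, 6, 40)
    b = rng.integers(0, 6, 60)
    pooled = op_distribution([a, b], w=3)
    assert np.array_equal(pooled.counts,
                          op_distribution(a, w=3).counts + op_distribution(b, w=3).counts)


def test_op_distribution_uniform_for_iid_noise(rng):
    idx = encode_ordinal_patterns(rng.standard_normal(100_000), OPConfig(w=3))
    p = op_distribution(idx, w=3, normalize=True).counts
    se = np.sqrt((1 / 6) * (5 / 6) / len(idx))
    assert np.all(np.abs(p - 1 / 6) < 4 * se)


def test_op_distribution_rejects_empty_and_out_of_range():
    with pytest.raises(ValueError):
        op_distribution(np.array([], dtype=int), w=3)
    with pytest.raises(ValueError):
        op_distribution(np.array([6]), w=3)


def test_joint_distribution_diagonal_marginals_and_independence(rng):
    idx = rng.integers(0, 6, 5000)
    joint = joint_op_distribution(idx, idx, w=3)
    assert np.all(joint.counts == np.diag(np.diag(joint.counts)))
    other = rng.integers(0, 6, 5000)
    joint = joint_op_distribution(idx, other, w=3)
    assert np.array_equal(joint.marginal(0).counts, op_distribution(idx, w=3).counts)
    assert np.array_equal(joint.marginal(1).counts, op_distribution(other, w=3).counts)
    # shuffling destroys dependence: chi-square not significant at alpha=0.01
    shuffled = rng.permutation(other[:10_000])
    joint = joint_op_distribution(idx[:10_000], shuffled, w=3)
    _, p, _, _ = chi2_contingency(joint.counts + 0.5)
    assert p > 0.01
    with pytest.raises(ValueError, match="length"):
        joint_op_distribution(idx, idx[:-1], w=3)


# --------------------------------------------------------------------- MI


def mi_double_sum_oracle(joint):
    """Independent elementwise summation of the MI definition."""
    p = joint / joint.sum()
    px, py = p.sum(1), p.sum(0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                total += p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
    return total


def test_mi_zero_for_outer_product(rng):
    p = rng.random(6)
    p /= p.sum()
    q = np.full(6, 1 / 6)
    joint = JointOPDistribution(np.outer(p, q), w=3)
    assert mutual_information(joint) == pytest.approx(0.0, abs=1e-12)


def test_mi_of_diagonal_joint_equals_marginal_entropy(rng):
    p = rng.random(6)
    joint = JointOPDistribution(np.diag(p), w=3)
    assert mutual_information(joint) == pytest.approx(shannon_entropy(p / p.sum()), abs=1e-12)


def test_mi_matches_double_sum_oracle():
    counts = np.zeros((6, 6))
    counts[:2, :2] = [[0.4, 0.1], [0.1, 0.4]]
    joint = JointOPDistribution(counts, w=3)
    assert mutual_information(joint) == pytest.approx(mi_double_sum_oracle(counts), abs=1e-12)


# ------------------------------------------------------------- adjacency


def test_mi_adjacency_duplicate_channel_and_symmetry(rng):
    x = rng.standard_normal(3000)
    y = rng.standard_normal(3000)
    data = np.stack([x, x, y])[None, :, :]
    ts = TrialSet(data, 1000.0, ["a", "a2", "b"])
    adj = mi_adjacency(ts, OPConfig(w=3, lag=1))
    assert np.allclose(adj.values, adj.values.T)
    # duplicated channel: off-diagonal MI equals the diagonal entropy
    assert adj.values[0, 1] == pytest.approx(adj.values[0, 0], abs=1e-10)


def test_mi_adjacency_independent_channels_below_bias_bound(rng):
    n = 20_000
    data = rng.standard_normal((1, 2, n))
    ts = TrialSet(data, 1000.0, ["a", "b"])
    adj = mi_adjacency(ts, OPConfig(w=4, lag=1))
    n_pat = n - 3
    bound = (24 - 1) ** 2 / (2 * n_pat * np.log(2))
    assert adj.values[0, 1] < 3 * bound


def test_mi_adjacency_shared_source_exceeds_independent_pair(rng):
    t = np.arange(3000)
    shared = np.sin(2 * np.pi * 0.01 * t) + 0.3 * rng.standard_normal(3000)
    ch = [shared + 0.5 * rng.standard_normal(3000) for _ in range(2)]
    ch += [rng.standard_normal(3000) for _ in range(2)]
    ts = TrialSet(np.stack(ch)[None], 1000.0, list("abcd"))
    adj = mi_adjacency(ts, OPConfig(w=3, lag=10))
    assert adj.values[0, 1] > adj.values[2, 3]
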