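"""Structure Index: closed forms, brute-force oracle, shuffle calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripplemap.structure_index import (
    assign_bins,
    overlap_score_matrix,
    structure_index,
    structure_index_from_adjacency,
)


def brute_force_si(coords, values, n_bins, k):
    """Independent SI implementation: explicit distance matrix, explicit
    neighbor lists, no shared code with the production path."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    edges = np.linspace(values.min(), values.max(), n_bins + 1)
    bin_of = np.zeros(len(values), dtype=int)
    for i, v in enumerate(values):
        for b in range(n_bins):
            lo, hi = edges[b], edges[b + 1]
            if (v >= lo and v < hi) or (b == n_bins - 1 and v == hi):
                bin_of[i] = b
    labels = sorted({b for b in bin_of})
    n = len(labels)
    A = np.zeros((n, n))
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    for a_i, a in enumerate(labels):
        for b_i, b in enumerate(labels):
            if a_i == b_i:
                continue
            U = [i for i in range(len(values)) if bin_of[i] == a]
            V = [i for i in range(len(values)) if bin_of[i] == b]
            total = 0
            for u in U:
                # stable sort preserves U-then-V order among distance ties,
                # the same convention the production path uses
                pool = [p for p in U + V if p != u]
                pool.sort(key=lambda p: d2[u, p])
                kk = min(k, len(pool))
                total += sum(1 for p in pool[:kk] if p in V)
            A[a_i, b_i] = total / (len(U) * min(k, len(U) + len(V) - 1))
    si = max(0.0, 1.0 - (2.0 / (n**2 - n)) * A.sum())
    return si, A


@pytest.mark.parametrize("trial", range(4))
def test_matches_brute_force_oracle(trial):
    """Exact agreement with the enumeration oracle for N <= 50."""
    rng = np.random.default_rng(100 + trial)
    n = rng.integers(30, 51)
    coords = rng.normal(size=(n, 3))
    values = rng.normal(size=n)
    k = int(rng.integers(3, 8))
    n_bins = int(rng.integers(3, 6))
    si_ref, A_ref = brute_force_si(coords, values, n_bins, k)
    res = structure_index(coords, values, n_bins=n_bins, k=k)
    np.testing.assert_allclose(res.adjacency, A_ref, atol=1e-12)
    assert res.si == pytest.approx(si_ref, abs=1e-12)


def test_lattice_hand_enumeration():
    """30-point 1D lattice, feature = coordinate, 3 bins, k=3: only the
    border point of each bin pair sees one cross-bin neighbor. E.g. for
    u = 9 (bin 0 vs bin 1), the 3 nearest in bins 0 u 1 are {8, 10, 7}
    (distance ties broken by index), one of which is in bin 1, and no other
    u in bin 0 reaches bin 1, so OS = 1 / (10 * 3); non-adjacent bins never
    overlap."""
    coords = np.arange(30.0)[:, None]
    values = np.arange(30.0)
    res = structure_index(coords, values, n_bins=3, k=3)
    si_ref, A_ref = brute_force_si(coords, values, 3, 3)
    np.testing.assert_allclose(res.adjacency, A_ref, atol=1e-12)
    assert res.adjacency[0, 1] == pytest.approx(1 / 30)
    assert res.adjacency[0, 2] == 0.0
    # SI = 1 - (2/(n^2-n)) * sum(A) = 1 - (1/3) * (4/30)
    assert res.si == pytest.approx(si_ref) == pytest.approx(1 - 8 / 180)


def test_fully_separated_bins_give_si_one():
    rng = np.random.default_rng(0)
    centers = np.arange(10) * 100.0
    coords = np.concatenate([rng.normal(c, 0.1, (20, 2)) + 0 for c in centers])
    values = np.repeat(np.arange(10.0), 20)
    res = structure_index(coords, values, n_bins=10, k=5)
    assert np.allclose(res.adjacency[~np.eye(10, dtype=bool)], 0.0)
    assert res.si == 1.0


def test_uniform_overlap_closed_form():
    n = 10
    A = np.full((n, n), 0.5)
    np.fill_diagonal(A, 0.0)
    assert structure_index_from_adjacency(A) == pytest.approx(0.0)
    assert structure_index_from_adjacency(np.zeros((n, n))) == 1.0
    with pytest.raises(ValueError):
        structure_index_from_adjacency(np.ones((3, 4)))
    bad = np.ones((3, 3))
    with pytest.raises(ValueError):
        structure_index_from_adjacency(bad)


def test_permuted_feature_loses_structure(ripple_cloud):
    sub = ripple_cloud.subset(np.arange(400))
    vals = sub.meta["frequency"].to_numpy()
    rng = np.random.default_rng(1)
    si_true = structure_index(sub.waveforms, vals).si
    si_perm = structure_index(sub.waveforms, rng.permutation(vals)).si
    assert si_true > si_perm + 0.3
    assert si_perm < 0.1


def test_monotone_transform_invariance_equal_count(ripple_cloud):
    sub = ripple_cloud.subset(np.arange(300))
    vals = sub.meta["frequency"].to_numpy()
    a = structure_index(sub.waveforms, vals, bin_mode="equal_count").si
    b = structure_index(sub.waveforms, np.exp(vals / 50), bin_mode="equal_count").si
    assert a == pytest.approx(b, abs=1e-12)


def test_constant_feature_rejected():
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError):
        structure_index(rng.normal(size=(50, 2)), np.ones(50))


def test_shuffles_optional_and_significant_gradient():
    rng = np.random.default_rng(3)
    coords = rng.normal(size=(150, 2))
    grad = coords[:, 0]
    res = structure_index(coords, grad, n_bins=5, k=10, n_shuffles=0)
    assert res.p_value is None and res.shuffle_values is None
    res = structure_index(coords, grad, n_bins=5, k=10, n_shuffles=30, seed=0)
    # a strong gradient beats every shuffle: p at the permutation floor
    assert res.p_value == pytest.approx(1 / 31)
    assert res.p_ttest < 0.01
    assert np.all(res.shuffle_values < res.si)
    with pytest.raises(ValueError):
        structure_index(coords, grad, n_shuffles=5)


def test_shuffle_type_i_error_calibrated():
    """Under the null (feature independent of position) the shuffle test
    rejects at about the nominal rate."""
    rng = np.random.default_rng(4)
    coords = rng.normal(size=(40, 2))
    rejections = 0
    n_rep = 60
    for rep in range(n_rep):
        vals = rng.normal(size=40)
        res = structure_index(coords, vals, n_bins=4, k=5, n_shuffles=25, seed=rep)
        rejections += res.p_value < 0.05
    rate = rejections / n_rep
    assert rate < 0.2  # ~0.05 nominal; binomial noise at n=60 allows drift


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_si_always_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(25, 80))
    coords = rng.normal(size=(n, int(rng.integers(1, 5))))
    vals = rng.normal(size=n)
    res = structure_index(coords, vals, n_bins=4, k=int(rng.integers(1, 10)))
    assert 0.0 <= res.si <= 1.0
    assert np.all(res.adjacency >= 0) and np.all(res.adjacency <= 1)
    assert np.all(np.diag(res.adjacency) == 0)


def test_equal_width_vs_equal_count_bins():
    vals = np.concatenate([np.zeros(90), np.array([10.0] * 10)])
    idx_w, edges_w = assign_bins(vals, 2, "equal_width")
    assert np.bincount(idx_w).tolist() == [90, 10]
    with pytest.raises(ValueError):
        assign_bins(vals, 1)
    with pytest.raises(ValueError):
        assign_bins(np.full(5, 3.0), 2)
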