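"""Projection operators against exhaustive oracles and their invariants."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from awge_espca import (
    GeneNetwork,
    PathwayWeights,
    awge_project,
    decay_omega,
    edge_norm,
    espca_project,
    normalize_weights,
    select_edges,
    sparse_project,
    weighted_edge_norm,
)

from conftest import random_network


# --- independent oracles -------------------------------------------------

def l0_project_oracle(z, s):
    """Exhaustive: the size-s index subset maximizing the kept energy."""
    z = np.asarray(z, dtype=float)
    best, best_val = None, -1.0
    for subset in combinations(range(len(z)), s):
        val = sum(z[i] ** 2 for i in subset)
        if val > best_val + 1e-15:
            best, best_val = subset, val
    out = np.zeros_like(z)
    out[list(best)] = z[list(best)]
    return out


def edge_subset_oracle(norms, k):
    """Exhaustive: the size-k edge subset with the largest total norm
    (first subset in lexicographic order on strict improvement)."""
    best, best_val = None, -1.0
    for subset in combinations(range(len(norms)), k):
        val = sum(norms[i] for i in subset)
        if val > best_val + 1e-12:
            best, best_val = subset, val
    return set(best)


# --- sparse_project ------------------------------------------------------

@pytest.mark.parametrize(
    "z, s, expected",
    [
        ([3, -5, 1, 2], 2, [3, -5, 0, 0]),
        ([0, 0, 0], 2, [0, 0, 0]),
        ([7], 1, [7]),
        ([1, 1, 1], 2, [1, 1, 0]),  # ties break toward the lower index
    ],
)
def test_sparse_project_examples(z, s, expected):
    np.testing.assert_array_equal(sparse_project(np.array(z, float), s), expected)


def test_sparse_project_rejects_bad_budget():
    with pytest.raises(ValueError):
        sparse_project(np.ones(3), 0)
    with pytest.raises(ValueError):
        sparse_project(np.ones(3), 4)


def test_sparse_project_matches_exhaustive_oracle(rng):
    for _ in range(1000):
        m = int(rng.integers(1, 9))
        s = int(rng.integers(1, m + 1))
        z = rng.standard_normal(m)
        np.testing.assert_array_equal(sparse_project(z, s), l0_project_oracle(z, s))


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    z=hnp.arrays(float, st.integers(1, 8),
                 elements=st.floats(-100, 100, allow_nan=False)),
    data=st.data(),
)
def test_sparse_project_keeps_values_unchanged(z, data):
    s = data.draw(st.integers(1, len(z)))
    out = sparse_project(z, s)
    kept = out != 0
    assert kept.sum() <= s
    np.testing.assert_array_equal(out[kept], z[kept])
    # kept energy equals the oracle's optimum even under ties
    oracle = l0_project_oracle(z, s)
    assert np.sum(out**2) == pytest.approx(np.sum(oracle**2))


# --- edge norms ----------------------------------------------------------

@pytest.mark.parametrize(
    "u, edge, expected",
    [((1.0, 2.0), (0, 1), 5.0), ((0.0, 0.0), (0, 1), 0.0), ((-3.0, 0.0), (0, 1), 9.0)],
)
def test_edge_norm_examples(u, edge, expected):
    assert edge_norm(np.array(u), edge) == expected


def test_edge_norm_out_of_range():
    with pytest.raises(IndexError):
        edge_norm(np.ones(2), (0, 5))


@pytest.mark.parametrize(
    "u, w, expected",
    [((1.0, 2.0), (1.0, 1.0), 5.0), ((1.0, 1.0), (1.0, 3.0), 4.0), ((0.0, 0.0), (9.0, 9.0), 0.0)],
)
def test_weighted_edge_norm_examples(u, w, expected):
    weights = PathwayWeights(counts=np.array(w), normalized=np.array(w))
    assert weighted_edge_norm(np.array(u), (0, 1), weights) == expected


def test_raising_a_count_never_lowers_that_probes_weight(rng):
    # own-weight monotonicity of the min-max normalisation
    for _ in range(200):
        counts = rng.integers(0, 20, size=6).astype(float)
        i = int(rng.integers(0, 6))
        bumped = counts.copy()
        bumped[i] += rng.integers(1, 5)
        if np.ptp(counts) == 0 or np.ptp(bumped) == 0:
            continue
        w0 = normalize_weights(counts).normalized[i]
        w1 = normalize_weights(bumped).normalized[i]
        assert w1 >= w0 - 1e-12


# --- espca_project -------------------------------------------------------

def test_espca_project_example():
    z = np.array([3.0, 1.0, 0.1, 5.0])
    net = GeneNetwork(np.array([[0, 1], [2, 3]]))
    out, sel = espca_project(z, net, 1)
    np.testing.assert_array_equal(out, [0, 0, 0.1, 5.0])
    assert set(sel.selected) == {1}


def test_espca_full_budget_keeps_all_covered_vertices(tiny_network):
    z = np.array([1.0, -2.0, 3.0, 0.0, 5.0, 6.0])
    out, _ = espca_project(z, tiny_network, tiny_network.n_edges)
    np.testing.assert_array_equal(out, z)


def test_espca_support_bound(rng):
    for _ in range(50):
        net = random_network(rng, 8, 5)
        z = rng.standard_normal(8)
        s = int(rng.integers(1, 6))
        out, sel = espca_project(z, net, s)
        support = set(np.flatnonzero(out))
        covered = set(net.edges[sel.selected].ravel())
        assert support <= covered
        assert len(support) <= 2 * s


def test_espca_matches_edge_subset_oracle(rng):
    for _ in range(100):
        m = int(rng.integers(4, 9))
        n_edges = int(rng.integers(1, 7))
        net = random_network(rng, m, n_edges)
        z = rng.standard_normal(m)
        s = int(rng.integers(1, n_edges + 1))
        norms = np.array([edge_norm(z, tuple(e)) for e in net.edges])
        _, sel = espca_project(z, net, s)
        assert set(sel.selected) == edge_subset_oracle(norms, s)


def test_espca_on_disjoint_edges_maximizes_kept_energy(rng):
    # with vertex-disjoint edges the top-k-by-norm selection also maximizes
    # the energy of the surviving vector over all edge subsets
    for _ in range(50):
        net = GeneNetwork(np.array([[0, 1], [2, 3], [4, 5]]), n_probes=6)
        z = rng.standard_normal(6)
        out, _ = espca_project(z, net, 2)
        best = max(
            np.sum(z[np.unique(net.edges[list(subset)].ravel())] ** 2)
            for subset in combinations(range(3), 2)
        )
        assert np.sum(out**2) == pytest.approx(best)


def test_espca_permutation_equivariance(rng):
    z = rng.standard_normal(6)
    net = GeneNetwork(np.array([[0, 1], [2, 3], [4, 5]]), n_probes=6)
    out, _ = espca_project(z, net, 2)
    perm = rng.permutation(6)
    inv = np.argsort(perm)
    znew = z[perm]
    edges_new = np.array([[inv[i], inv[j]] for i, j in net.edges])
    out_new, _ = espca_project(znew, GeneNetwork(edges_new, n_probes=6), 2)
    np.testing.assert_allclose(out_new, out[perm])


# --- select_edges / decay_omega ------------------------------------------

def test_select_edges_deterministic_topk():
    sel = select_edges(np.array([9.0, 7.0, 5.0, 1.0]), 2, omega=0.0)
    assert set(sel.selected) == {0, 1}


def test_select_edges_pool_excludes_low_norm_edges(rng):
    # omega=0.5, k=2 -> pool of ceil(3)=3; edge 3 can never be drawn
    seen = set()
    for _ in range(200):
        sel = select_edges(np.array([9.0, 7.0, 5.0, 1.0]), 2, omega=0.5, rng=rng)
        seen |= set(map(int, sel.selected))
        assert set(sel.candidate_pool) == {0, 1, 2}
    assert 3 not in seen
    assert seen == {0, 1, 2}


def test_select_edges_full_budget():
    sel = select_edges(np.array([3.0, 2.0, 1.0]), 3, omega=2.0, rng=np.random.default_rng(0))
    assert set(sel.selected) == {0, 1, 2}


def test_select_edges_rejects_bad_budget():
    with pytest.raises(ValueError):
        select_edges(np.ones(3), 4)


@pytest.mark.parametrize("omega, rho, expected", [(0.5, 0.2, 0.3), (0.1, 0.2, 0.0), (0.0, 0.7, 0.0)])
def test_decay_omega(omega, rho, expected):
    assert decay_omega(omega, rho) == pytest.approx(expected)


# --- awge_project --------------------------------------------------------

def test_awge_ablation_reduces_to_espca(rng):
    for _ in range(50):
        m = int(rng.integers(4, 9))
        net = random_network(rng, m, 5)
        z = rng.standard_normal(m)
        k = int(rng.integers(1, 6))
        out_e, sel_e = espca_project(z, net, k)
        out_a, sel_a = awge_project(z, net, None, k=k, omega=0.0,
                                    use_lar=False, use_weights=False)
        np.testing.assert_array_equal(out_a, out_e)
        assert set(sel_a.selected) == set(sel_e.selected)


def test_awge_matches_brute_force_with_lar_and_weights(rng):
    from awge_espca.regularizer import lar_regularize

    for _ in range(100):
        m = int(rng.integers(5, 9))
        n_edges = int(rng.integers(1, 7))
        net = random_network(rng, m, n_edges)
        z = rng.standard_normal(m) * 10
        k = int(rng.integers(1, n_edges + 1))
        weights = normalize_weights(rng.integers(0, 10, size=m).astype(float))
        out, sel = awge_project(z, net, weights, k=k, omega=0.0, lq=0.3)
        zl = lar_regularize(z, 0.3)
        norms = np.array([weighted_edge_norm(zl, tuple(e), weights) for e in net.edges])
        assert set(sel.selected) == edge_subset_oracle(norms, k)
        covered = np.unique(net.edges[sorted(sel.selected)].ravel())
        expect = np.zeros(m)
        expect[covered] = zl[covered]
        np.testing.assert_array_equal(out, expect)


def test_awge_project_deterministic_at_zero_omega(rng, tiny_network):
    z = rng.standard_normal(6)
    w = normalize_weights(np.arange(6, dtype=float))
    a = awge_project(z, tiny_network, w, k=2, omega=0.0)
    b = awge_project(z, tiny_network, w, k=2, omega=0.0)
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1].selected, b[1].selected)
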