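"""Generalized modularity, null models and Louvain optimization."""

import itertools

import numpy as np
import pytest

from hicomm import community as comm
from hicomm import contacts as cm

from conftest import random_symmetric_map

FG = comm.NullModelSpec("FG", 1.0)
NG = comm.NullModelSpec("NG")


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def fg_null_brute(a, alpha):
    """Term-by-term double-loop evaluation of the FG null model."""
    n = a.shape[0]
    k = a.sum(axis=1)
    m = k.sum() / 2
    z = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                z += k[i] * k[j] * abs(i - j) ** (-alpha)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                p[i, j] = 2 * m * k[i] * k[j] * abs(i - j) ** (-alpha) / z
    return p


def modularity_brute(a, p, labels, gamma):
    n = a.shape[0]
    m = a.sum() / 2
    q = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and labels[i] == labels[j]:
                q += a[i, j] - gamma * p[i, j]
    return q / (2 * m)


def set_partitions(items):
    """All set partitions (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [[first] + block] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_q(cmap, spec, gamma):
    """Optimum of Q over every partition of the unmasked nodes."""
    a = cmap.matrix.copy()
    np.fill_diagonal(a, 0.0)
    m = a.sum() / 2
    p = comm.null_matrix(cmap, spec)
    b = a - gamma * p
    n = a.shape[0]
    best = -np.inf
    for part in set_partitions(list(range(n))):
        q = sum(b[np.ix_(block, block)].sum() for block in part) / (2 * m)
        if q > best:
            best = q
            best_part = part
    return best, best_part


def clique_pair(k, bridge=False):
    """Two k-cliques, optionally joined by a single edge."""
    n = 2 * k
    a = np.zeros((n, n))
    for block in (range(k), range(k, n)):
        for i, j in itertools.combinations(block, 2):
            a[i, j] = a[j, i] = 1.0
    if bridge:
        a[k - 1, k] = a[k, k - 1] = 1.0
    return cm.ContactMap(a)


def ring(n):
    a = np.zeros((n, n))
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1.0
    return cm.ContactMap(a)


def chain_graph(n):
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1.0
    return cm.ContactMap(a)


# ---------------------------------------------------------------------------
# strengths and nulls
# ---------------------------------------------------------------------------

class TestStrengths:
    def test_balanced_map_has_unit_strengths(self, fg_small_balanced):
        bal = fg_small_balanced[0]
        k, m = comm.strengths(bal)
        keep = bal.unmasked()
        np.testing.assert_allclose(k[keep], 1.0, atol=1e-6)
        assert 2 * m == pytest.approx(keep.sum(), rel=1e-6)

    def test_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        k, m = comm.strengths(cm.ContactMap(a))
        np.testing.assert_allclose(k, 2.0)
        assert m == 3.0

    def test_matches_row_sums(self, rng):
        cmap = random_symmetric_map(rng, 10)
        k, _ = comm.strengths(cmap)
        np.testing.assert_allclose(k, cmap.matrix.sum(axis=1))


class TestNullMatrix:
    def test_fg_normalization(self, rng):
        cmap = random_symmetric_map(rng, 17, masked=(4,))
        _, m = comm.strengths(cmap)
        p = comm.null_matrix(cmap, FG)
        assert p.sum() == pytest.approx(2 * m, rel=1e-9)

    def test_fg_alpha_to_zero_is_ng_shaped(self, rng):
        cmap = random_symmetric_map(rng, 9)
        k, _ = comm.strengths(cmap)
        p = comm.null_matrix(cmap, comm.NullModelSpec("FG", 1e-9))
        kk = np.outer(k, k)
        np.fill_diagonal(kk, 0.0)
        ratio = p[kk > 0] / kk[kk > 0]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-6)

    def test_fg_matches_double_loop_oracle(self):
        a = np.zeros((4, 4))
        for i in range(3):
            a[i, i + 1] = a[i + 1, i] = 1.0
        cmap = cm.ContactMap(a)
        p = comm.null_matrix(cmap, FG)
        np.testing.assert_allclose(p, fg_null_brute(a, 1.0), atol=1e-12)

    def test_ng_against_networkx(self, rng):
        """NG-null modularity agrees with networkx's implementation."""
        import networkx as nx

        cmap = random_symmetric_map(rng, 12)
        labels = rng.integers(0, 3, size=12)
        part = comm.Partition(labels, gamma=1.0)
        ours = comm.modularity(cmap, part, NG, gamma=1.0)
        g = nx.from_numpy_array(cmap.matrix)
        communities = [set(np.where(labels == c)[0]) for c in range(3)]
        theirs = nx.community.modularity(g, communities, weight="weight")
        # networkx includes i == j null terms: correct for the convention
        k, m = comm.strengths(cmap)
        diag_null = np.sum(k * k) / (2 * m) ** 2
        assert ours == pytest.approx(theirs + diag_null, abs=1e-10)


# ---------------------------------------------------------------------------
# modularity values
# ---------------------------------------------------------------------------

class TestModularity:
    def test_one_community_fg_is_one_minus_gamma(self, rng):
        for gamma in (0.0, 0.4, 1.0, 1.7):
            cmap = random_symmetric_map(rng, 13, masked=(6,))
            labels = np.zeros(13, dtype=int)
            labels[6] = comm.MASKED_LABEL
            part = comm.Partition(labels, gamma=gamma)
            q = comm.modularity(cmap, part, FG, gamma)
            assert q == pytest.approx(1.0 - gamma, abs=1e-12)

    def test_singletons_give_zero(self, rng):
        cmap = random_symmetric_map(rng, 8)
        part = comm.Partition(np.arange(8), gamma=1.0)
        assert comm.modularity(cmap, part, FG, 1.0) == 0.0

    def test_two_clique_ng_matches_brute_force(self):
        cmap = clique_pair(4, bridge=True)
        labels = np.array([0] * 4 + [1] * 4)
        p = comm.null_matrix(cmap, NG)
        expected = modularity_brute(cmap.matrix, p, labels, 1.0)
        part = comm.Partition(labels, gamma=1.0)
        assert comm.modularity(cmap, part, NG, 1.0) == pytest.approx(
            expected, abs=1e-12)

    def test_bounded_on_random_partitions(self, rng):
        cmap = random_symmetric_map(rng, 15)
        for _ in range(200):
            labels = rng.integers(0, 5, size=15)
            part = comm.Partition(labels, gamma=0.8)
            q = comm.modularity(cmap, part, FG, 0.8)
            assert -1.0 - 1e-12 <= q <= 1.0 + 1e-12

    def test_label_permutation_invariance(self, rng):
        cmap = random_symmetric_map(rng, 12)
        labels = rng.integers(0, 4, size=12)
        relabel = rng.permutation(4)
        q1 = comm.modularity(cmap, comm.Partition(labels, 1.0), FG, 1.0)
        q2 = comm.modularity(cmap, comm.Partition(relabel[labels], 1.0),
                             FG, 1.0)
        assert q1 == pytest.approx(q2, abs=1e-14)


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

class TestLouvain:
    def test_disconnected_cliques_recovered_exactly(self):
        cmap = clique_pair(4, bridge=False)
        part = comm.louvain(cmap, NG, 1.0, seed=0)
        labels = part.labels
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        best_q, _ = exhaustive_best_q(cmap, NG, 1.0)
        assert part.Q == pytest.approx(best_q, abs=1e-9)

    def test_gamma_zero_single_community(self, rng):
        cmap = random_symmetric_map(rng, 10)
        part = comm.louvain(cmap, FG, 0.0, seed=1)
        assert part.n_communities == 1
        assert part.Q == pytest.approx(1.0, abs=1e-12)

    def test_never_beats_exhaustive_on_small_graphs(self):
        for cmap in [clique_pair(3, bridge=True), ring(7), chain_graph(6)]:
            best_q, _ = exhaustive_best_q(cmap, NG, 1.0)
            part = comm.louvain(cmap, NG, 1.0, seed=3, n_restarts=5)
            assert part.Q <= best_q + 1e-9

    def test_dominates_trivial_partitions(self, fg_small_balanced):
        bal = fg_small_balanced[0]
        for gamma in (0.4, 0.8):
            part = comm.louvain(bal, FG, gamma, seed=2, n_restarts=2)
            assert part.Q >= max(0.0, 1.0 - gamma) - 1e-12

    def test_deterministic_given_seed(self, fg_small_balanced):
        bal = fg_small_balanced[1]
        a = comm.louvain(bal, FG, 0.6, seed=5, n_restarts=2)
        b = comm.louvain(bal, FG, 0.6, seed=5, n_restarts=2)
        assert np.array_equal(a.labels, b.labels) and a.Q == b.Q

    def test_masked_bins_get_sentinel(self, rng):
        cmap = random_symmetric_map(rng, 12, masked=(0, 5))
        part = comm.louvain(cmap, FG, 0.5, seed=0, n_restarts=2)
        assert part.labels[0] == comm.MASKED_LABEL
        assert part.labels[5] == comm.MASKED_LABEL
        assert np.all(part.labels[cmap.unmasked()] >= 0)

    def test_empty_graph_raises(self):
        cmap = cm.ContactMap(np.zeros((4, 4)), mask=np.ones(4, dtype=bool))
        with pytest.raises(ValueError):
            comm.louvain(cmap, FG, 0.5)

    def test_gamma_resolution_effect(self, fg_small_balanced):
        """Larger gamma values yield smaller (or equal) median communities."""
        medians = []
        for gamma in (0.4, 0.8):
            sizes = []
            for bal in fg_small_balanced:
                part = comm.louvain(bal, FG, gamma, seed=7, n_restarts=2)
                sizes.extend(part.sizes())
            medians.append(np.median(sizes))
        assert medians[0] >= medians[1]


class TestGammaScan:
    def test_single_gamma_equals_direct_call(self, fg_small_balanced):
        bal = fg_small_balanced[2]
        parts, table = comm.gamma_scan(bal, FG, [0.6], seed=4, n_restarts=2)
        direct = comm.louvain(bal, FG, 0.6, seed=4, n_restarts=2)
        assert np.array_equal(parts[0].labels, direct.labels)
        assert table.loc[0, "Q"] == direct.Q

    def test_empty_map_error_propagates(self):
        cmap = cm.ContactMap(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            comm.gamma_scan(cmap, FG, [0.4, 0.6])

    def test_summary_schema(self, fg_small_balanced):
        _, table = comm.gamma_scan(fg_small_balanced[0], FG, [0.5, 0.7],
                                   seed=1, n_restarts=2)
        assert list(table["gamma"]) == [0.5, 0.7]
        assert {"n_communities", "median_size", "Q"} <= set(table.columns)
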