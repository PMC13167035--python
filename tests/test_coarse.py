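import numpy as np
import pytest
import scipy.sparse as sp

from superclust.coarse import (
    bcd_optimize,
    expand_labels,
    finch_init,
    fuse_laplacian,
    labels_to_indicator,
    laplacian,
    objective,
    row_update_scores,
    supercell_similarity,
    update_weights,
)
from superclust.supercells import SupercellAssignment


def make_assignment(supercell_of):
    supercell_of = np.asarray(supercell_of)
    return SupercellAssignment(supercell_of, int(supercell_of.max()) + 1)


def random_laplacians(rng, S, V=2, density=0.4):
    Ls, AS_sum = [], None
    for _ in range(V):
        W = rng.random((S, S)) * (rng.random((S, S)) < density)
        W = W + W.T
        np.fill_diagonal(W, 0)
        AS = sp.csr_matrix(W)
        Ls.append(laplacian(AS))
        AS_sum = AS if AS_sum is None else AS_sum + AS
    return Ls, AS_sum


class TestSupercellSimilarity:
    def test_singletons_recover_symmetrized_graph(self, rng):
        A = sp.random(8, 8, density=0.4, random_state=1, format="csr")
        A.setdiag(0)
        sc = make_assignment(np.arange(8))
        AS = supercell_similarity(A, sc).toarray()
        expected = (A + A.T).toarray()
        np.fill_diagonal(expected, 0)
        np.testing.assert_allclose(AS, expected)

    def test_hand_blocks(self):
        A = np.zeros((3, 3))
        A[0, 2], A[2, 0], A[1, 2], A[2, 1] = 0.3, 0.1, 0.4, 0.2
        sc = make_assignment([0, 0, 1])
        AS = supercell_similarity(sp.csr_matrix(A), sc).toarray()
        assert AS[0, 1] == pytest.approx(0.3 + 0.1 + 0.4 + 0.2)
        assert AS[0, 0] == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        n, S = 20, 6
        A = sp.random(n, n, density=0.3, random_state=3, format="csr")
        A.setdiag(0)
        assign = rng.integers(0, S, size=n)
        assign[:S] = np.arange(S)  # every supercell nonempty
        sc = make_assignment(assign)
        AS = supercell_similarity(A, sc).toarray()
        Ad = A.toarray()
        expected = np.zeros((S, S))
        for y in range(S):
            for z in range(S):
                if y == z:
                    continue
                for i in np.nonzero(assign == y)[0]:
                    for j in np.nonzero(assign == z)[0]:
                        expected[y, z] += Ad[i, j] + Ad[j, i]
        np.testing.assert_allclose(AS, expected, atol=1e-12)


class TestLaplacian:
    def test_zero_graph(self):
        L = laplacian(sp.csr_matrix((3, 3)))
        assert L.nnz == 0

    def test_two_node_graph(self):
        AS = sp.csr_matrix(np.array([[0.0, 2.5], [2.5, 0.0]]))
        L = laplacian(AS).toarray()
        np.testing.assert_allclose(L, [[2.5, -2.5], [-2.5, 2.5]])

    def test_null_vector(self, rng):
        W = rng.random((10, 10))
        W = W + W.T
        np.fill_diagonal(W, 0)
        L = laplacian(sp.csr_matrix(W))
        np.testing.assert_allclose(np.asarray(L.sum(axis=1)).ravel(), 0.0, atol=1e-12)


class TestObjectiveAndWeights:
    def test_single_cluster_zero(self, rng):
        Ls, _ = random_laplacians(rng, 8, V=1)
        E = labels_to_indicator(np.zeros(8, dtype=int), 1)
        assert objective(E, Ls, np.array([1.0])) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_cut_zero(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        Ls = [laplacian(sp.csr_matrix(W))]
        E = labels_to_indicator(np.array([0, 0, 1, 1]), 2)
        assert objective(E, Ls, np.array([1.0])) == pytest.approx(0.0, abs=1e-12)

    def test_l1_objective_is_twice_the_cut(self, rng):
        # ||L e_p||_1 sums boundary mass from both sides of the cut
        W = rng.random((10, 10))
        W = W + W.T
        np.fill_diagonal(W, 0)
        Ls = [laplacian(sp.csr_matrix(W))]
        labels = rng.integers(0, 3, size=10)
        labels[:3] = [0, 1, 2]
        E = labels_to_indicator(labels, 3)
        cut = sum(
            W[i, j]
            for i in range(10)
            for j in range(10)
            if labels[i] != labels[j]
        )
        assert objective(E, Ls, np.array([1.0])) == pytest.approx(2 * cut)

    def test_single_modality_weight_one(self, rng):
        Ls, _ = random_laplacians(rng, 6, V=1)
        E = labels_to_indicator(np.array([0, 1, 0, 1, 0, 1]), 2)
        w = update_weights(E, Ls)
        assert w.omega[0] == pytest.approx(1.0)

    def test_hand_weights(self):
        # modality objectives (1, 3): weights (4, 4/3), harmonic constraint holds
        L1 = sp.csr_matrix(np.array([[0.25, -0.25], [-0.25, 0.25]]))
        L2 = sp.csr_matrix(np.array([[0.75, -0.75], [-0.75, 0.75]]))
        E = labels_to_indicator(np.array([0, 1]), 2)
        w = update_weights(E, [L1, L2])
        np.testing.assert_allclose(w.epsilon, [1.0, 3.0])
        np.testing.assert_allclose(w.omega, [4.0, 4.0 / 3.0])
        assert np.sum(1.0 / w.omega) == pytest.approx(1.0, abs=1e-12)

    def test_harmonic_constraint_random(self, rng):
        Ls, _ = random_laplacians(rng, 12, V=3)
        labels = rng.integers(0, 3, size=12)
        labels[:3] = [0, 1, 2]
        w = update_weights(labels_to_indicator(labels, 3), Ls)
        assert np.sum(1.0 / w.omega) == pytest.approx(1.0, abs=1e-12)

    def test_zero_epsilon_capped(self):
        # first modality already perfectly cut: huge but finite weight
        W1 = np.zeros((4, 4))
        W1[0, 1] = W1[1, 0] = 1.0
        W2 = np.ones((4, 4)) - np.eye(4)
        Ls = [laplacian(sp.csr_matrix(W1)), laplacian(sp.csr_matrix(W2))]
        E = labels_to_indicator(np.array([0, 0, 1, 1]), 2)
        w = update_weights(E, Ls)
        assert np.isfinite(w.omega).all()
        assert w.omega[0] > 1e10
        assert np.sum(1.0 / w.omega) == pytest.approx(1.0, abs=1e-9)


class TestFuseLaplacian:
    def test_single_symmetric_doubles(self, rng):
        Ls, _ = random_laplacians(rng, 6, V=1)
        Lhat = fuse_laplacian(Ls, np.array([1.0])).toarray()
        np.testing.assert_allclose(Lhat, 2 * Ls[0].toarray(), atol=1e-12)

    def test_symmetric_and_null_vector(self, rng):
        Ls, _ = random_laplacians(rng, 9, V=3)
        Lhat = fuse_laplacian(Ls, np.array([1.0, 2.0, 0.5])).toarray()
        np.testing.assert_allclose(Lhat, Lhat.T, atol=1e-12)
        np.testing.assert_allclose(Lhat.sum(axis=1), 0.0, atol=1e-10)


class TestRowUpdate:
    def brute_scores(self, Lhat, labels, d, C):
        """Full recomputation: quadratic form with row d set to cluster i,
        minus the form with row d unassigned."""
        Ld = np.asarray(Lhat.todense())
        S = len(labels)
        out = np.zeros(C)
        for i in range(C):
            for variant, sign in ((i, 1.0), (None, -1.0)):
                E = labels_to_indicator(labels, C)
                E[d] = 0.0
                if variant is not None:
                    E[d, variant] = 1.0
                col = E[:, i]
                out[i] += sign * float(col @ Ld @ col)
        return out

    def test_incremental_matches_full(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            S, C = int(rng.integers(4, 10)), int(rng.integers(2, 5))
            W = rng.random((S, S))
            W = W + W.T
            np.fill_diagonal(W, 0)
            Lhat = sp.csc_matrix(laplacian(sp.csr_matrix(W)))
            labels = rng.integers(0, C, size=S)
            labels[:C] = np.arange(C)
            d = int(rng.integers(0, S))
            scores = row_update_scores(Lhat, labels, d, C)
            np.testing.assert_allclose(scores, self.brute_scores(Lhat, labels, d, C), atol=1e-9)

    def test_two_supercells_merge_forbidden(self):
        # single positive edge: merging is optimal but would empty a cluster
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        Ls = [laplacian(sp.csr_matrix(W))]
        labels, w, trace = bcd_optimize(Ls, np.array([0, 1]), 2, max_iter=5, min_iter=1)
        assert sorted(labels) == [0, 1]  # both clusters still populated

    def test_fixed_point_unchanged(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        Ls = [laplacian(sp.csr_matrix(W))]
        labels, _, trace = bcd_optimize(Ls, np.array([0, 0, 1, 1]), 2, max_iter=12)
        np.testing.assert_array_equal(labels, [0, 0, 1, 1])
        assert trace.objective[-1] == pytest.approx(0.0, abs=1e-12)


class TestFinchInit:
    def test_two_separated_pairs(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        labels = finch_init(sp.csr_matrix(W), 2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_c_equals_s(self):
        W = sp.csr_matrix(np.ones((5, 5)) - np.eye(5))
        labels = finch_init(W, 5)
        assert sorted(labels) == list(range(5))

    def test_contract_exactly_c_nonempty(self, rng):
        for trial in range(10):
            r = np.random.default_rng(trial)
            S, C = int(r.integers(6, 20)), int(r.integers(2, 6))
            W = r.random((S, S)) * (r.random((S, S)) < 0.5)
            W = W + W.T
            np.fill_diagonal(W, 0)
            labels = finch_init(sp.csr_matrix(W), C)
            assert len(labels) == S
            assert sorted(set(labels)) == list(range(C))

    def test_more_clusters_than_supercells(self):
        W = sp.csr_matrix((3, 3))
        with pytest.raises(ValueError, match="cannot form"):
            finch_init(W, 4)


class TestBcdOptimize:
    def test_objective_non_increasing_random(self):
        for trial in range(50):
            rng = np.random.default_rng(100 + trial)
            S, C = int(rng.integers(8, 25)), int(rng.integers(2, 5))
            Ls, AS_sum = random_laplacians(rng, S, V=int(rng.integers(1, 4)))
            labels0 = finch_init(AS_sum, C)
            _, _, trace = bcd_optimize(Ls, labels0, C)
            obj = np.array(trace.objective)
            assert np.all(np.diff(obj) <= 1e-9 * np.maximum(1.0, np.abs(obj[:-1])))

    def test_one_move_optimal(self):
        rng = np.random.default_rng(11)
        S, C = 6, 2
        Ls, AS_sum = random_laplacians(rng, S, V=2)
        labels, w, _ = bcd_optimize(Ls, finch_init(AS_sum, C), C)
        Ew = labels_to_indicator(labels, C)
        base = objective(Ew, Ls, w.omega)
        sizes = np.bincount(labels, minlength=C)
        for d in range(S):
            for c in range(C):
                if c == labels[d] or sizes[labels[d]] == 1:
                    continue
                alt = labels.copy()
                alt[d] = c
                assert objective(labels_to_indicator(alt, C), Ls, w.omega) >= base - 1e-9

    def test_weight_constraint_every_iteration(self, rng):
        Ls, AS_sum = random_laplacians(rng, 15, V=3)
        _, w, trace = bcd_optimize(Ls, finch_init(AS_sum, 3), 3)
        for om in trace.weights:
            assert np.sum(1.0 / om) == pytest.approx(1.0, abs=1e-12)

    def test_determinism(self, rng):
        Ls, AS_sum = random_laplacians(rng, 20, V=2)
        out1 = bcd_optimize(Ls, finch_init(AS_sum, 3), 3)
        out2 = bcd_optimize(Ls, finch_init(AS_sum, 3), 3)
        np.testing.assert_array_equal(out1[0], out2[0])
        assert out1[2].objective == out2[2].objective

    def test_well_separated_converges_fast(self):
        # block-diagonal similarity: near-stationary within a few iterations
        rng = np.random.default_rng(2)
        blocks = [rng.random((5, 5)) + 0.5 for _ in range(3)]
        W = sp.block_diag([b + b.T for b in blocks]).toarray()
        np.fill_diagonal(W, 0)
        Ls = [laplacian(sp.csr_matrix(W))]
        labels0 = finch_init(sp.csr_matrix(W), 3)
        labels, _, trace = bcd_optimize(Ls, labels0, 3)
        assert trace.objective[-1] == pytest.approx(0.0, abs=1e-9)
        assert abs(trace.objective[min(4, len(trace.objective) - 1)] - trace.objective[-1]) <= 1e-9


class TestCellLevelConsistency:
    def test_singleton_coarsening_preserves_objective(self, rng):
        # with all-singleton supercells and V=1, the coarse objective equals
        # the cell-level cut objective for any partition
        n = 12
        A = sp.random(n, n, density=0.4, random_state=8, format="csr")
        A.setdiag(0)
        sc = make_assignment(np.arange(n))
        AS = supercell_similarity(A, sc)
        L_coarse = laplacian(AS)
        B = A + A.T
        B.setdiag(0)
        L_cell = laplacian(B)
        labels = rng.integers(0, 3, size=n)
        E = labels_to_indicator(labels, 3)
        assert objective(E, [L_coarse], np.array([1.0])) == pytest.approx(
            objective(E, [L_cell], np.array([1.0]))
        )


class TestExpandLabels:
    def test_all_one_cluster(self):
        sc = make_assignment([0, 1, 1, 2])
        out = expand_labels(np.zeros(3, dtype=int), sc)
        np.testing.assert_array_equal(out, 0)

    def test_histogram_weighted_by_supercell_sizes(self):
        sc = make_assignment([0, 0, 1, 2, 2, 2])
        out = expand_labels(np.array([0, 1, 1]), sc)
        np.testing.assert_array_equal(np.bincount(out), [2, 4])

    def test_length_mismatch(self):
        sc = make_assignment([0, 1])
        with pytest.raises(ValueError):
            expand_labels(np.array([0]), sc)
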