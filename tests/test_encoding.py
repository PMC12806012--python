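"""Laplacian PE, graph-encoder embedding, SVD compression, SPE assembly."""

import numpy as np
import pytest

import networkx as nx

from spenet import encoding as enc
from spenet import graph_data as gd
from conftest import random_graph


def laplacian_of(g):
    return enc.normalized_laplacian(gd.adjacency_matrix(g))


class TestNormalizedLaplacian:
    def test_single_edge_closed_form(self):
        g = gd.build_interactome(["a", "b"], [("a", "b")])
        L = laplacian_of(g).matrix
        assert np.allclose(L, [[1, -1], [-1, 1]])
        vals = np.linalg.eigvalsh(L)
        assert np.allclose(vals, [0.0, 2.0], atol=1e-12)

    def test_complete_graph_spectrum(self, triangle):
        vals = np.linalg.eigvalsh(laplacian_of(triangle).matrix)
        assert np.allclose(vals, [0.0, 1.5, 1.5], atol=1e-12)

    def test_zero_multiplicity_counts_components(self):
        g = gd.build_interactome(
            ["a", "b", "c", "d"], [("a", "b"), ("c", "d")]
        )
        vals = np.linalg.eigvalsh(laplacian_of(g).matrix)
        assert int(np.sum(np.abs(vals) < 1e-10)) == 2

    def test_asymmetric_rejected(self):
        A = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            enc.normalized_laplacian(A)

    def test_isolated_node_identity_row(self):
        g = gd.build_interactome(["a", "b", "c"], [("a", "b")])
        L = laplacian_of(g).matrix
        assert np.allclose(L[2], [0, 0, 1])

    def test_spectral_properties_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            g = random_graph(rng, int(rng.integers(5, 61)), p=0.2)
            L = laplacian_of(g)
            vals, vecs = np.linalg.eigh(L.matrix)
            assert np.allclose(L.matrix, L.matrix.T, atol=1e-12)
            assert vals.min() > -1e-10 and vals.max() < 2 + 1e-10
            G = nx.Graph()
            G.add_nodes_from(range(g.n_nodes))
            G.add_edges_from(g.edges)
            # isolated nodes get an identity row (eigenvalue exactly 1),
            # so the zero eigenspace counts the non-singleton components
            n_comp = sum(1 for c in nx.connected_components(G) if len(c) > 1)
            assert int(np.sum(vals < 1e-8)) == n_comp


class TestLaplacianPE:
    def test_single_edge_eigenvector(self):
        g = gd.build_interactome(["a", "b"], [("a", "b")])
        lpe = enc.laplacian_pe(laplacian_of(g), k=1)
        assert np.allclose(lpe.eigenvalues, [2.0])
        v = 1.0 / np.sqrt(2.0)
        assert np.allclose(np.abs(lpe.vectors[:, 0]), [v, v])
        # sign fix: largest-magnitude entry (first on tie) positive
        assert lpe.vectors[0, 0] > 0

    def test_zero_eigenvalue_never_selected(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = random_graph(rng, 30, p=0.2)
            L = laplacian_of(g)
            vals = np.linalg.eigvalsh(L.matrix)
            avail = int(np.sum(vals > 1e-8 * max(vals.max(), 1)))
            lpe = enc.laplacian_pe(L, k=min(5, avail))
            assert lpe.eigenvalues.min() > 1e-8

    def test_matches_dense_solver_subspaces(self):
        rng = np.random.default_rng(11)
        g = random_graph(rng, 30, p=0.25)
        L = laplacian_of(g)
        lpe = enc.laplacian_pe(L, k=5)
        vals, vecs = np.linalg.eigh(L.matrix)  # independent dense oracle
        keep = vals > 1e-8 * vals.max()
        ref_vals = vals[keep][:5]
        ref_vecs = vecs[:, keep][:, :5]
        assert np.allclose(lpe.eigenvalues, ref_vals, atol=1e-10)
        # principal angles for simple eigenvalues
        for i in range(5):
            simple = np.sum(np.abs(ref_vals - ref_vals[i]) < 1e-9) == 1
            if simple:
                cos = abs(lpe.vectors[:, i] @ ref_vecs[:, i])
                assert cos > 1 - 1e-6

    def test_orthonormal_columns(self):
        rng = np.random.default_rng(13)
        g = random_graph(rng, 40, p=0.2)
        lpe = enc.laplacian_pe(laplacian_of(g), k=8)
        gram = lpe.vectors.T @ lpe.vectors
        assert np.allclose(gram, np.eye(8), atol=1e-8)

    def test_k_too_large_reports_available(self):
        g = gd.build_interactome(["a", "b"], [("a", "b")])
        with pytest.raises(ValueError, match="1"):
            enc.laplacian_pe(laplacian_of(g), k=2)

    def test_sparse_path_matches_dense(self, monkeypatch):
        """Force the iterative solver and compare against the dense one."""
        rng = np.random.default_rng(17)
        g = random_graph(rng, 80, p=0.1)
        L = laplacian_of(g)
        dense = enc.laplacian_pe(L, k=6)
        monkeypatch.setattr(enc, "DENSE_EIG_LIMIT", 10)
        sparse = enc.laplacian_pe(L, k=6)
        assert np.allclose(sparse.eigenvalues, dense.eigenvalues, atol=1e-8)
        for i in range(6):
            cos = abs(sparse.vectors[:, i] @ dense.vectors[:, i])
            assert cos > 1 - 1e-6


class TestGEE:
    def test_weight_matrix_toy(self, triangle):
        dm = gd.build_disease_map([("dX", "a"), ("dX", "b"), ("dY", "c")], triangle)
        W = enc.gee_weight_matrix(dm, 3).W
        assert np.allclose(W, [[0.5, 0], [0.5, 0], [0, 1]])

    def test_columns_sum_to_one(self, path_graph):
        dm = gd.build_disease_map(
            [("dX", "g1"), ("dX", "g2"), ("dX", "g3"), ("dY", "g4"), ("dY", "g1")],
            path_graph,
        )
        W = enc.gee_weight_matrix(dm, 4).W
        assert np.allclose(W.sum(axis=0), 1.0)

    def test_overlapping_node_two_nonzeros(self, path_graph):
        dm = gd.build_disease_map([("dX", "g1"), ("dY", "g1"), ("dY", "g2")], path_graph)
        W = enc.gee_weight_matrix(dm, 4).W
        g1 = path_graph.index_of("g1")
        assert np.count_nonzero(W[g1]) == 2

    def test_embedding_path_toy(self):
        # P3 (0-1-2), dX = {0, 1}, dY = {2}: Z = A W computed by hand
        g = gd.build_interactome(["a", "b", "c"], [("a", "b"), ("b", "c")])
        dm = gd.build_disease_map([("dX", "a"), ("dX", "b"), ("dY", "c")], g)
        A = gd.adjacency_matrix(g)
        Z = enc.gee_embedding(A, enc.gee_weight_matrix(dm, 3))
        assert np.allclose(Z, [[0.5, 0], [0.5, 1], [0.5, 0]])

    def test_entries_are_neighbor_counts(self):
        rng = np.random.default_rng(23)
        g = random_graph(rng, 30, p=0.2)
        assoc = [(f"d{k}", g.node_ids[i]) for k in range(4)
                 for i in rng.choice(30, size=6, replace=False)]
        dm = gd.build_disease_map(assoc, g)
        A = gd.adjacency_matrix(g)
        Z = enc.gee_embedding(A, enc.gee_weight_matrix(dm, 30))
        nbrs = g.neighbors()
        for i in range(30):
            for j, members in enumerate(dm.member_arrays()):
                expect = len(set(nbrs[i]) & set(members)) / len(members)
                assert Z[i, j] == pytest.approx(expect)
                assert Z[i, j] <= len(nbrs[i]) / len(members) + 1e-12

    def test_empty_graph_gives_zero(self):
        g = gd.build_interactome(["a", "b", "c"], [])
        dm = gd.build_disease_map([("dX", "a"), ("dY", "b")], g)
        Z = enc.gee_embedding(gd.adjacency_matrix(g), enc.gee_weight_matrix(dm, 3))
        assert not Z.any()

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(29)
        g = random_graph(rng, 25, p=0.2)
        assoc = [(f"d{k}", g.node_ids[i]) for k in range(5)
                 for i in rng.choice(25, size=5, replace=False)]
        dm = gd.build_disease_map(assoc, g)
        A = gd.adjacency_matrix(g)
        Z = enc.gee_embedding(A, enc.gee_weight_matrix(dm, 25))
        # permuting disease order permutes Z's columns identically
        perm = rng.permutation(dm.n_diseases)
        dm2 = gd.DiseaseMap(
            diseases=tuple(dm.diseases[p] for p in perm),
            members=tuple(dm.members[p] for p in perm),
        )
        Z2 = enc.gee_embedding(A, enc.gee_weight_matrix(dm2, 25))
        assert np.allclose(Z2, Z[:, perm])


class TestGPE:
    def test_diagonal_svd(self):
        Z = np.diag([3.0, 2.0, 1.0])
        g = enc.gpe(Z, d=2)
        assert np.allclose(g.singular_values, [3.0, 2.0])
        assert np.allclose(np.abs(g.vectors), np.eye(3)[:, :2])

    def test_rank_one(self):
        u = np.array([1.0, 2.0, -1.0])
        v = np.array([0.5, 1.5])
        g = enc.gpe(np.outer(u, v), d=1)
        direction = g.vectors[:, 0]
        cos = abs(direction @ u) / np.linalg.norm(u)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_best_rank_d_approximation(self):
        rng = np.random.default_rng(31)
        Z = rng.normal(size=(20, 8))
        g = enc.gpe(Z, d=4)
        proj = g.vectors @ (g.vectors.T @ Z)
        err = np.linalg.norm(Z - proj)
        U, S, Vt = np.linalg.svd(Z)  # oracle
        best = np.linalg.norm(Z - (U[:, :4] * S[:4]) @ Vt[:4])
        assert err == pytest.approx(best, abs=1e-8)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(37)
        Z = rng.normal(size=(15, 6))
        g1 = enc.gpe(Z, d=3)
        g2 = enc.gpe(Z[:, rng.permutation(6)], d=3)
        assert np.allclose(g1.singular_values, g2.singular_values, atol=1e-10)
        # same left subspace
        P1 = g1.vectors @ g1.vectors.T
        P2 = g2.vectors @ g2.vectors.T
        assert np.allclose(P1, P2, atol=1e-8)

    def test_d_out_of_range(self):
        with pytest.raises(ValueError):
            enc.gpe(np.eye(4), d=5)


class TestAssembleEncoding:
    def test_nope_identity(self):
        M = np.arange(12.0).reshape(4, 3)
        b = enc.assemble_encoding(M, variant="NoPE")
        assert (b.E == M).all() and b.d_model == 3

    def test_spe_dimensions_and_blocks(self):
        rng = np.random.default_rng(41)
        g = random_graph(rng, 30, p=0.3)
        A = gd.adjacency_matrix(g)
        M = rng.normal(size=(30, 8))
        lpe = enc.laplacian_pe(enc.normalized_laplacian(A), k=8)
        zeros_gpe = enc.GPEMatrix(vectors=np.zeros((30, 2)), singular_values=np.zeros(2))
        b = enc.assemble_encoding(M, lpe, zeros_gpe, variant="SPE")
        assert b.d_model == 10
        assert np.allclose(b.E[:, :8], M + lpe.vectors)
        assert not b.E[:, 8:].any()

    def test_defaults_give_72(self):
        rng = np.random.default_rng(43)
        M = rng.normal(size=(100, 64))
        lpe = enc.LPEMatrix(vectors=rng.normal(size=(100, 64)), eigenvalues=np.arange(64) + 0.1)
        gpe_m = enc.GPEMatrix(vectors=rng.normal(size=(100, 8)), singular_values=np.ones(8))
        assert enc.assemble_encoding(M, lpe, gpe_m, variant="SPE").d_model == 72

    def test_dimension_mismatch_reports_sizes(self):
        M = np.zeros((5, 4))
        lpe = enc.LPEMatrix(vectors=np.zeros((5, 3)), eigenvalues=np.ones(3))
        with pytest.raises(ValueError, match="3"):
            enc.assemble_encoding(M, lpe, None, variant="LPE")


def test_node_relabeling_equivariance():
    """One node permutation permutes rows of LPE, Z, GPE and E identically
    (up to per-column sign for the eigen/singular vectors)."""
    rng = np.random.default_rng(47)
    g = random_graph(rng, 20, p=0.3)
    A = gd.adjacency_matrix(g)
    assoc = [(f"d{k}", g.node_ids[i]) for k in range(4)
             for i in rng.choice(20, size=5, replace=False)]
    dm = gd.build_disease_map(assoc, g)
    perm = rng.permutation(20)
    P = np.eye(20)[perm]
    A2 = P @ A @ P.T

    Z = enc.gee_embedding(A, enc.gee_weight_matrix(dm, 20))
    dm2 = gd.DiseaseMap(
        diseases=dm.diseases,
        members=tuple(
            frozenset(int(np.nonzero(perm == i)[0][0]) for i in m) for m in dm.members
        ),
    )
    Z2 = enc.gee_embedding(A2, enc.gee_weight_matrix(dm2, 20))
    assert np.allclose(Z2, P @ Z, atol=1e-12)

    lpe = enc.laplacian_pe(enc.normalized_laplacian(A), k=4)
    lpe2 = enc.laplacian_pe(enc.normalized_laplacian(A2), k=4)
    for i in range(4):
        simple = np.sum(np.abs(lpe.eigenvalues - lpe.eigenvalues[i]) < 1e-9) == 1
        if simple:
            cos = abs(lpe2.vectors[:, i] @ (P @ lpe.vectors[:, i]))
            assert cos > 1 - 1e-8
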