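import numpy as np
import pytest

from promgraph.embeddings import (EmbeddingMatrix, MultiScaleEmbedder,
                                  concat_embeddings, generate_biased_walks,
                                  grarep_embed, modularity_matrix,
                                  skipgram_embed, socdim_embed)


def weighted_triangle():
    A = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
    return A


def two_cliques(n_per=10, bridge_weight=0.5):
    m = 2 * n_per
    A = np.zeros((m, m))
    A[:n_per, :n_per] = 1.0
    A[n_per:, n_per:] = 1.0
    np.fill_diagonal(A, 0)
    A[n_per - 1, n_per] = A[n_per, n_per - 1] = bridge_weight
    return A


class TestBiasedWalks:
    def test_walk_length_one(self):
        corpus = generate_biased_walks(weighted_triangle(), walk_length=1,
                                       walks_per_node=2, seed=0)
        assert all(len(w) == 1 for w in corpus.walks)
        assert len(corpus.walks) == 6

    def test_walks_stay_on_edges(self):
        A = two_cliques()
        corpus = generate_biased_walks(A, p=0.5, q=2.0, walks_per_node=3,
                                       walk_length=12, seed=1)
        for walk in corpus.walks:
            for a, b in zip(walk, walk[1:]):
                assert A[a, b] > 0

    def test_first_step_transition_frequencies(self):
        """With p=q=1 empirical one-step frequencies match edge-weight ratios."""
        A = weighted_triangle()
        corpus = generate_biased_walks(A, p=1.0, q=1.0, walks_per_node=2000,
                                       walk_length=2, seed=3)
        counts = np.zeros((3, 3))
        for a, b in corpus.walks:
            counts[a, b] += 1
        empirical = counts / counts.sum(axis=1, keepdims=True)
        expected = A / A.sum(axis=1, keepdims=True)
        assert np.abs(empirical - expected).sum(axis=1).max() < 0.05

    def test_return_parameter_bias(self):
        """Small p makes immediate backtracking much more likely."""
        A = weighted_triangle()
        back = {"low": 0, "high": 0}
        for tag, p in (("low", 0.05), ("high", 20.0)):
            corpus = generate_biased_walks(A, p=p, q=1.0, walks_per_node=500,
                                           walk_length=3, seed=4)
            back[tag] = sum(w[0] == w[2] for w in corpus.walks if len(w) == 3)
        assert back["low"] > back["high"]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_biased_walks(weighted_triangle(), p=0.0)


class TestSkipgram:
    def test_shape_and_determinism(self):
        corpus = generate_biased_walks(two_cliques(), walks_per_node=3,
                                       walk_length=10, seed=5)
        a = skipgram_embed(corpus, n_nodes=20, dim=8, epochs=2, seed=6)
        b = skipgram_embed(corpus, n_nodes=20, dim=8, epochs=2, seed=6)
        assert a.vectors.shape == (20, 8)
        np.testing.assert_array_equal(a.vectors, b.vectors)
        assert a.column_names[0] == "GraphEmbeddings_0"

    def test_cliques_are_separated(self):
        A = two_cliques(bridge_weight=0.2)
        corpus = generate_biased_walks(A, walks_per_node=10, walk_length=20, seed=7)
        emb = skipgram_embed(corpus, n_nodes=20, dim=8, epochs=5, seed=8).vectors
        norm = emb / np.linalg.norm(emb, axis=1, keepdims=True)
        cos = norm @ norm.T
        within = (cos[:10, :10].sum() - 10) / 90 + (cos[10:, 10:].sum() - 10) / 90
        across = cos[:10, 10:].mean() * 2
        assert within / 2 > across / 2

    def test_empty_corpus_rejected(self):
        from promgraph.embeddings import WalkCorpus

        with pytest.raises(ValueError):
            skipgram_embed(WalkCorpus([], 1, 1, 0, 0, 0))


class TestSocDim:
    def test_modularity_sum_zero(self, rng):
        for _ in range(20):
            m = int(rng.integers(5, 30))
            A = rng.random((m, m)) * (rng.random((m, m)) < 0.4)
            A = np.maximum(A, A.T)
            np.fill_diagonal(A, 0)
            if A.sum() == 0:
                continue
            assert abs(modularity_matrix(A).sum()) < 1e-8

    def test_two_block_sign_separation(self):
        A = two_cliques(bridge_weight=1.0)
        emb = socdim_embed(A, k=1).vectors[:, 0]
        agreement = max((np.sign(emb[:10]) > 0).sum() + (np.sign(emb[10:]) < 0).sum(),
                        (np.sign(emb[:10]) < 0).sum() + (np.sign(emb[10:]) > 0).sum())
        assert agreement >= 19

    def test_shape_and_sign_determinism(self):
        A = two_cliques()
        a = socdim_embed(A, k=3).vectors
        b = socdim_embed(A, k=3).vectors
        np.testing.assert_array_equal(a, b)
        assert a.shape == (20, 3)
        assert socdim_embed(A, k=1).vectors.shape == (20, 1)

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            socdim_embed(two_cliques(), k=20)


class TestGraRep:
    def test_transition_rows_stochastic(self, rng):
        A = two_cliques()
        deg = A.sum(axis=1)
        S = A / deg[:, None]
        St = np.eye(len(A))
        for _ in range(4):
            St = St @ S
            np.testing.assert_allclose(St.sum(axis=1), 1.0, atol=1e-10)

    def test_shape_contract(self, rng):
        m = 30
        A = rng.random((m, m)) * 0.5
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        emb = grarep_embed(A, max_step=2, dim_per_step=4)
        assert emb.vectors.shape == (30, 8)

    def test_barbell_clustering_recovers_cliques(self):
        from sklearn.cluster import KMeans

        A = two_cliques(bridge_weight=0.3)
        emb = grarep_embed(A, max_step=3, dim_per_step=4).vectors
        labels = KMeans(2, n_init=10, random_state=0).fit_predict(emb)
        truth = np.array([0] * 10 + [1] * 10)
        agreement = max((labels == truth).mean(), (labels != truth).mean())
        assert agreement >= 0.9

    def test_rank_deficient_zero_padding(self):
        A = weighted_triangle()
        emb = grarep_embed(A, max_step=1, dim_per_step=10)
        assert emb.vectors.shape == (3, 10)
        assert np.all(np.isfinite(emb.vectors))


class TestConcat:
    def _mat(self, m, d, tag):
        return EmbeddingMatrix(np.full((m, d), float(d)), tag,
                               [f"GraphEmbeddings_{k}" for k in range(d)])

    def test_width_arithmetic(self):
        out = concat_embeddings(
            [self._mat(5, 8, "node"), self._mat(5, 4, "community"), self._mat(5, 8, "global")]
        )
        assert out.vectors.shape == (5, 20)
        assert out.column_names == [f"GraphEmbeddings_{k}" for k in range(20)]

    def test_canonical_order_regardless_of_call_order(self):
        a = concat_embeddings([self._mat(4, 2, "global"), self._mat(4, 3, "node")])
        b = concat_embeddings([self._mat(4, 3, "node"), self._mat(4, 2, "global")])
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_single_part_identity(self):
        part = self._mat(4, 3, "community")
        out = concat_embeddings([part])
        np.testing.assert_array_equal(out.vectors, part.vectors)

    def test_row_mismatch(self):
        with pytest.raises(ValueError):
            concat_embeddings([self._mat(4, 2, "node"), self._mat(5, 2, "global")])


class TestMultiScaleEmbedder:
    def test_selected_scales_and_determinism(self):
        A = two_cliques()
        emb1 = MultiScaleEmbedder(scales=("community", "global"), community_k=4,
                                  global_max_step=2, global_dim_per_step=4,
                                  seed=3).fit_transform(A)
        emb2 = MultiScaleEmbedder(scales=("community", "global"), community_k=4,
                                  global_max_step=2, global_dim_per_step=4,
                                  seed=3).fit_transform(A)
        assert emb1.vectors.shape == (20, 12)
        np.testing.assert_array_equal(emb1.vectors, emb2.vectors)

    def test_no_scales_zero_width(self):
        emb = MultiScaleEmbedder(scales=()).fit_transform(two_cliques())
        assert emb.vectors.shape == (20, 0)
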