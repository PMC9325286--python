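"""Clustering backends, UMAP reduction, elbow selection, bounds warnings."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from nephrotext import cluster_engine as ce
from nephrotext.preprocess import vectorize
from tests.conftest import make_token_docs


@pytest.fixture(scope="module")
def two_group_matrices():
    docs = make_token_docs([0] * 10 + [1] * 10, seed=3)
    return vectorize(docs, "tfidf"), vectorize(docs, "count"), np.repeat([0, 1], 10)


class TestKMeans:
    def test_disjoint_vocabulary_recovered(self, two_group_matrices):
        tfidf, _, y = two_group_matrices
        cs = ce.cluster_kmeans(tfidf, k=2, seed=0)
        assert adjusted_rand_score(y, cs.labels) == 1.0
        assert cs.corpus_size_kept == 20  # no outliers for k-means

    def test_k_equals_n_singletons(self, two_group_matrices):
        tfidf, _, _ = two_group_matrices
        cs = ce.cluster_kmeans(tfidf, k=20, seed=0)
        assert cs.n_clusters == 20

    def test_determinism_and_k_validation(self, two_group_matrices):
        tfidf, _, _ = two_group_matrices
        a = ce.cluster_kmeans(tfidf, k=3, seed=5).labels
        b = ce.cluster_kmeans(tfidf, k=3, seed=5).labels
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            ce.cluster_kmeans(tfidf, k=1, seed=0)
        with pytest.raises(ValueError):
            ce.cluster_kmeans(tfidf, k=21, seed=0)


class TestLDA:
    def test_tfidf_input_rejected(self, two_group_matrices):
        tfidf, _, _ = two_group_matrices
        with pytest.raises(ValueError, match="count"):
            ce.cluster_lda(tfidf, k=2)

    def test_k1_single_topic(self, two_group_matrices):
        _, counts, _ = two_group_matrices
        cs = ce.cluster_lda(counts, k=1, seed=0, n_init=1, max_iter=10)
        assert set(cs.labels) == {0}

    def test_generative_recovery(self, two_group_matrices):
        _, counts, y = two_group_matrices
        cs = ce.cluster_lda(counts, k=2, seed=0)
        assert adjusted_rand_score(y, cs.labels) == 1.0


class TestUMAPReduce:
    def test_fixed_seed_bitwise_repeatable(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 20))
        a = ce.reduce_umap(X, d=2, n_neighbors=10, seed=4).matrix
        b = ce.reduce_umap(X, d=2, n_neighbors=10, seed=4).matrix
        assert np.array_equal(a, b)

    def test_separated_blobs_stay_separated(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.3, (40, 10)),
                       rng.normal(8, 0.3, (40, 10))])
        y = np.repeat([0, 1], 40)
        E = ce.reduce_umap(X, d=2, n_neighbors=10, seed=0).matrix
        # brute-force nearest neighbour purity in the reduced space
        d2 = ((E[:, None, :] - E[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        purity = (y[d2.argmin(axis=1)] == y).mean()
        assert purity >= 0.95

    def test_too_few_documents_rejected(self):
        with pytest.raises(ValueError):
            ce.reduce_umap(np.zeros((5, 3)), n_neighbors=15)


class TestHDBSCAN:
    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(c, 0.2, (30, 3)) for c in (0, 5, 10)])
        y = np.repeat([0, 1, 2], 30)
        cs = ce.cluster_hdbscan(
            ce.ReducedEmbedding(matrix=X, params={}, seed=0), min_cluster_size=5)
        kept = cs.kept_mask
        assert cs.n_clusters == 3
        assert adjusted_rand_score(y[kept], cs.labels[kept]) == 1.0
        sizes = np.bincount(cs.labels[kept])
        assert (sizes >= 5).all()

    def test_uniform_noise_mostly_outliers(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(120, 6))
        cs = ce.cluster_hdbscan(
            ce.ReducedEmbedding(matrix=X, params={}, seed=0), min_cluster_size=10)
        assert (cs.labels == ce.OUTLIER).mean() > 0.5

    def test_min_cluster_size_validated(self):
        with pytest.raises(ValueError):
            ce.cluster_hdbscan(
                ce.ReducedEmbedding(matrix=np.zeros((10, 2)), params={}, seed=0),
                min_cluster_size=1)


class TestElbow:
    def test_planted_group_count_recovered(self):
        docs = make_token_docs(list(np.repeat(range(5), 25)), words_per_group=8,
                               seed=6)
        tfidf = vectorize(docs, "tfidf")
        assert ce.select_k_elbow(tfidf, range(2, 13), seed=0) == 5

    def test_flat_curve_falls_back_with_warning(self, two_group_matrices):
        tfidf, _, _ = two_group_matrices
        with pytest.warns(UserWarning, match="flat"):
            k = ce.select_k_elbow(tfidf, [2, 3, 4], inertias=[5.0, 5.0, 5.0])
        assert k == 2

    def test_analytic_kink_found(self, two_group_matrices):
        tfidf, _, _ = two_group_matrices
        # piecewise linear with a sharp corner at k=3
        ks = [2, 3, 4, 5, 6]
        inertias = [100.0, 20.0, 18.0, 16.0, 14.0]
        assert ce.select_k_elbow(tfidf, ks, inertias=inertias) == 3

    def test_short_range_rejected(self, two_group_matrices):
        tfidf, _, _ = two_group_matrices
        with pytest.raises(ValueError):
            ce.select_k_elbow(tfidf, [2, 3])


class TestBoundsAndPersistence:
    @pytest.mark.parametrize("k,expect_warning", [(16, False), (7, True),
                                                  (10, False), (20, False),
                                                  (21, True)])
    def test_cluster_count_band(self, k, expect_warning):
        cs = ce.ClusterSet(labels=np.arange(k), method="m")
        assert bool(ce.check_cluster_bounds(cs)) == expect_warning

    def test_clusterset_roundtrip(self, tmp_path):
        cs = ce.ClusterSet(labels=np.array([0, 1, -1, 1]), method="hdbscan",
                           params={"min_cluster_size": 5}, seed=3,
                           doc_ids=["a", "b", "c", "d"])
        ce.save_clusterset(cs, tmp_path / "cs.json")
        back = ce.load_clusterset(tmp_path / "cs.json")
        assert np.array_equal(back.labels, cs.labels)
        assert back.method == cs.method and back.params == cs.params
        assert back.corpus_size_kept == 3 and back.n_clusters == 2

    def test_external_embedding_ingest(self, tmp_path):
        M = np.arange(12, dtype=float).reshape(4, 3)
        np.savetxt(tmp_path / "emb.txt", M)
        (tmp_path / "ids.txt").write_text("a\nb\nc\nd\n")
        emb = ce.load_external_embedding(tmp_path / "emb.txt", tmp_path / "ids.txt")
        assert emb.source == "external"
        assert np.array_equal(emb.matrix, M)
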