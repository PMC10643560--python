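import numpy as np
import pytest

from ikgm import embedding as emb
from ikgm.tokenization import Document


def _doc(sentences, view=1, sid="sp", label="A"):
    return Document(
        sid, label, view, tuple((f"p{i}", tuple(s)) for i, s in enumerate(sentences))
    )


def _paired_corpus(n=100, seed=0):
    """Tokens A,B always co-occur (amid one filler pool); C,D always
    co-occur amid a different pool, so each pair shares its contexts."""
    rng = np.random.default_rng(seed)
    pool1 = [f"X{i}" for i in range(8)]
    pool2 = [f"Y{i}" for i in range(8)]
    sentences = []
    for _ in range(n):
        if rng.random() < 0.5:
            s = ["A", "B"] + list(rng.choice(pool1, size=2))
        else:
            s = ["C", "D"] + list(rng.choice(pool2, size=2))
        rng.shuffle(s)
        sentences.append(s)
    return _doc(sentences)


class TestSkipgram:
    def test_cooccurring_tokens_are_closer(self):
        model = emb.train_skipgram(
            [_paired_corpus()], dim=16, window=3, min_count=2, epochs=10, seed=0
        )

        def cos(a, b):
            va, vb = model.vector_of(a), model.vector_of(b)
            return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))

        assert cos("A", "B") > cos("A", "C")

    def test_pair_structure_recovered_across_seeds(self):
        # distributional sanity: within-pair beats between-pair in >= 9/10 seeds
        wins = 0
        for seed in range(10):
            model = emb.train_skipgram(
                [_paired_corpus(seed=seed)], dim=16, window=3, min_count=2,
                epochs=10, seed=seed,
            )

            def cos(a, b):
                va, vb = model.vector_of(a), model.vector_of(b)
                return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))

            if cos("A", "B") > cos("A", "C") and cos("C", "D") > cos("B", "D"):
                wins += 1
        assert wins >= 9

    def test_below_min_count_token_becomes_unk(self):
        doc = _doc([["A", "B"], ["A", "B"], ["RARE", "A"]])
        model = emb.train_skipgram([doc], dim=4, window=2, min_count=2, epochs=1, seed=0)
        assert "RARE" not in model.vocabulary
        assert np.all(model.vector_of("RARE") == 0.0)

    def test_deterministic_under_fixed_seed(self):
        doc = _paired_corpus()
        m1 = emb.train_skipgram([doc], dim=8, window=2, epochs=2, seed=3)
        m2 = emb.train_skipgram([doc], dim=8, window=2, epochs=2, seed=3)
        np.testing.assert_array_equal(m1.vectors, m2.vectors)

    def test_retained_vectors_finite_and_nonzero(self):
        model = emb.train_skipgram([_paired_corpus()], dim=8, window=2, epochs=2, seed=0)
        norms = np.linalg.norm(model.vectors[1:], axis=1)
        assert np.all(norms > 0) and np.all(np.isfinite(model.vectors))

    def test_empty_vocabulary_rejected(self):
        doc = _doc([["X", "Y"]])
        with pytest.raises(ValueError, match="vocabulary"):
            emb.train_skipgram([doc], dim=4, min_count=5, seed=0)

    def test_mixed_views_rejected(self):
        with pytest.raises(ValueError, match="views"):
            emb.train_skipgram([_doc([["A"]], view=1), _doc([["A"]], view=2)], dim=4)


class TestEmbedDocument:
    def test_shapes_and_order(self):
        corpus = _paired_corpus()
        model = emb.train_skipgram([corpus], dim=8, window=2, epochs=1, seed=0)
        doc = _doc([["A", "B", "FILL"], ["C", "D", "A", "B", "FILL"]])
        mats = emb.embed_document(doc, model)
        assert [m.shape for m in mats] == [(3, 8), (5, 8)]
        np.testing.assert_array_equal(mats[0][0], model.vector_of("A"))

    def test_all_oov_sentence_is_zero_with_warning(self):
        corpus = _paired_corpus()
        model = emb.train_skipgram([corpus], dim=8, window=2, epochs=1, seed=0)
        doc = _doc([["ZZZ", "QQQ"]])
        with pytest.warns(UserWarning, match="out of vocabulary"):
            mats = emb.embed_document(doc, model)
        assert np.all(mats[0] == 0.0)

    def test_view_mismatch_rejected(self):
        corpus = _paired_corpus()
        model = emb.train_skipgram([corpus], dim=8, window=2, epochs=1, seed=0)
        with pytest.raises(ValueError, match="view"):
            emb.embed_document(_doc([["A"]], view=2), model)

    def test_reencoding_bitwise_reproducible(self):
        corpus = _paired_corpus()
        model = emb.train_skipgram([corpus], dim=8, window=2, epochs=1, seed=0)
        doc = _doc([["A", "B"]])
        a = emb.embed_document(doc, model)
        b = emb.embed_document(doc, model)
        np.testing.assert_array_equal(a[0], b[0])


class TestDiagnostics:
    def _blob_model(self, K=3, per=8, dim=6, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.normal(scale=20, size=(K, dim))
        vecs = np.concatenate(
            [centers[k] + rng.normal(scale=0.1, size=(per, dim)) for k in range(K)]
        )
        vocab = {f"t{i:02d}": i + 1 for i in range(K * per)}
        return emb.EmbeddingModel(
            view=1, dim=dim, vocabulary=vocab,
            vectors=np.vstack([np.zeros(dim), vecs]),
        ), np.repeat(np.arange(K), per)

    def test_separated_blobs_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        model, truth = self._blob_model()
        df = emb.embedding_diagnostics(model, K=3, seed=0)
        assert adjusted_rand_score(truth, df["cluster"]) == 1.0

    def test_projection_variance_ordering(self):
        model, _ = self._blob_model()
        df = emb.embedding_diagnostics(model, K=3, seed=0)
        assert {"token", "cluster", "pc1", "pc2"} <= set(df.columns)
        assert df["pc1"].var() >= df["pc2"].var()

    def test_k_one_single_cluster(self):
        model, _ = self._blob_model()
        df = emb.embedding_diagnostics(model, K=1, seed=0)
        assert set(df["cluster"]) == {0}

    def test_vocab_smaller_than_k_rejected(self):
        model, _ = self._blob_model(K=1, per=2)
        with pytest.raises(ValueError, match="< K"):
            emb.embedding_diagnostics(model, K=5)


def test_embedding_save_load_roundtrip(tmp_path):
    model = emb.train_skipgram([_paired_corpus()], dim=8, window=2, epochs=1, seed=0)
    path = tmp_path / "emb.txt"
    emb.save_embedding(model, path)
    back = emb.load_embedding(path)
    assert back.vocabulary == model.vocabulary
    np.testing.assert_allclose(back.vectors, model.vectors)
    assert (back.view, back.dim, back.window) == (model.view, model.dim, model.window)
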