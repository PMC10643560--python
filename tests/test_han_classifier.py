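import numpy as np
import pandas as pd
import pytest

import ikgm._autodiff as ad
from ikgm import han_classifier as han
from ikgm.embedding import EmbeddingModel
from ikgm.tokenization import Document


def _tiny_config(**kw):
    defaults = dict(
        embed_dim=3, word_hidden=2, sent_hidden=2, attn_dim=3,
        chunk_size=512, max_words_per_sentence=None, seed=0,
    )
    defaults.update(kw)
    return han.HANConfig(**defaults)


def _random_doc(rng, n_sent, max_words, dim):
    return [
        rng.normal(size=(int(rng.integers(1, max_words + 1)), dim))
        for _ in range(n_sent)
    ]


class TestNormalization:
    @pytest.mark.parametrize("case_seed", range(20))
    def test_all_softmax_normalizations_hold(self, case_seed):
        """Word attentions, sentence attentions and class probabilities each
        sum to one for random parameters and random ragged documents."""
        rng = np.random.default_rng(case_seed)
        cfg = _tiny_config(
            embed_dim=int(rng.integers(2, 6)),
            word_hidden=int(rng.integers(1, 4)),
            sent_hidden=int(rng.integers(1, 4)),
            attn_dim=int(rng.integers(2, 5)),
        )
        params = han.init_params(cfg, rng)
        doc = _random_doc(rng, int(rng.integers(1, 7)), 5, cfg.embed_dim)
        out = han.forward(doc, params, cfg)
        for alpha in out.word_attn:
            assert alpha.sum() == pytest.approx(1.0, abs=1e-6)
            assert (alpha >= 0).all()
        assert out.sent_attn.sum() == pytest.approx(1.0, abs=1e-6)
        assert (out.sent_attn >= 0).all()
        assert out.probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_word_sentence_attention_is_one(self):
        rng = np.random.default_rng(0)
        cfg = _tiny_config()
        params = han.init_params(cfg, rng)
        alpha, s = han.word_encode(rng.normal(size=(1, 3)), params, cfg)
        assert alpha.tolist() == [1.0]
        assert s.shape == (4,)

    def test_single_sentence_attention_is_one(self):
        rng = np.random.default_rng(0)
        cfg = _tiny_config()
        params = han.init_params(cfg, rng)
        alpha, P = han.sentence_encode(rng.normal(size=(1, 4)), params, cfg)
        assert alpha.tolist() == [1.0]
        assert P.shape == (4,)

    def test_zero_parameters_give_uniform_probabilities(self):
        cfg = _tiny_config()
        params = han.zero_params(cfg)
        doc = [np.ones((2, 3)), np.ones((3, 3))]
        out = han.forward(doc, params, cfg)
        np.testing.assert_allclose(out.probs, [0.5, 0.5], atol=1e-12)

    def test_softmax_arithmetic_on_injected_scores(self):
        # scores (ln 2, 0) must normalize to (2/3, 1/3)
        scores = ad.tensor(np.array([[np.log(2.0)], [0.0]]))
        alpha = ad.masked_softmax(scores, np.ones((2, 1), dtype=bool), axis=0)
        np.testing.assert_allclose(alpha.data.ravel(), [2 / 3, 1 / 3], atol=1e-12)

    def test_permuting_identical_sentences_keeps_attention_multiset(self):
        rng = np.random.default_rng(1)
        cfg = _tiny_config()
        params = han.init_params(cfg, rng)
        a = rng.normal(size=(3, 3))
        b = rng.normal(size=(2, 3))
        out1 = han.forward([a, a.copy(), b], params, cfg)
        out2 = han.forward([a.copy(), a, b], params, cfg)
        assert sorted(out1.sent_attn.round(12)) == sorted(out2.sent_attn.round(12))


class TestChunking:
    @pytest.mark.parametrize("doc_seed", range(5))
    def test_chunked_matches_monolithic(self, doc_seed):
        """Blockwise attention scoring with a global softmax is numerically
        identical to the single-block pass, for documents up to 10x the
        chunk size."""
        rng = np.random.default_rng(doc_seed)
        cfg_mono = _tiny_config(chunk_size=1000)
        cfg_chunk = _tiny_config(chunk_size=7)
        params = han.init_params(cfg_mono, rng)
        n_sent = int(rng.integers(40, 71))  # up to 10 x chunk_size
        doc = _random_doc(rng, n_sent, 4, 3)
        out_mono = han.forward(doc, params, cfg_mono)
        out_chunk = han.forward(doc, params, cfg_chunk)
        np.testing.assert_allclose(
            out_mono.sent_attn, out_chunk.sent_attn, atol=1e-6
        )
        np.testing.assert_allclose(out_mono.probs, out_chunk.probs, atol=1e-6)


class TestGradients:
    def test_numeric_vs_analytic_gradient(self):
        """Full-network gradient check on a 2-sentence x 3-word network."""
        rng = np.random.default_rng(0)
        cfg = _tiny_config(embed_dim=3, word_hidden=4, sent_hidden=4, attn_dim=4)
        params = han.init_params(cfg, rng)
        docs = [
            [rng.normal(size=(3, 3)), rng.normal(size=(2, 3))],
            [rng.normal(size=(3, 3))],
        ]
        y = np.array([0, 1])

        def loss_value():
            logits, _ = han.forward_batch(docs, params, cfg)
            return han._cross_entropy(logits, y)

        loss = loss_value()
        for p in params.values():
            p.grad = None
        ad.backward(loss)

        eps = 1e-6
        for name, p in params.items():
            analytic = p.grad if p.grad is not None else np.zeros_like(p.data)
            flat = p.data.ravel()
            idx = np.linspace(0, flat.size - 1, min(flat.size, 6)).astype(int)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_value().data
                flat[i] = orig - eps
                lm = loss_value().data
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert analytic.ravel()[i] == pytest.approx(
                    numeric, abs=1e-4, rel=1e-4
                ), name


class TestTraining:
    def _separable_docs(self, n_per_class=8, seed=0):
        """Label-determining token: class A documents contain a marker
        vector in one sentence, class B documents do not."""
        rng = np.random.default_rng(seed)
        marker = np.ones(4) * 2.0
        docs, labels = [], []
        for i in range(n_per_class * 2):
            label = "A" if i < n_per_class else "B"
            doc = [rng.normal(scale=0.3, size=(3, 4)) for _ in range(4)]
            if label == "A":
                doc[int(rng.integers(4))][1] = marker
            docs.append(doc)
            labels.append(label)
        return docs, labels

    def test_separable_fixture_reaches_perfect_training_accuracy(self):
        docs, labels = self._separable_docs()
        cfg = han.HANConfig(
            embed_dim=4, word_hidden=4, sent_hidden=4, attn_dim=4,
            learning_rate=1e-2, epochs=30, patience=30, batch_size=4,
            val_fraction=0.25, max_words_per_sentence=None, seed=0,
        )
        params, history = han.train_han(docs, labels, cfg)
        logits, _ = han.forward_batch(docs, params, cfg)
        pred = logits.data.argmax(axis=1)
        truth = np.array([0 if l == "A" else 1 for l in labels])
        assert (pred == truth).mean() == 1.0

    def test_marker_sentence_receives_max_attention(self):
        docs, labels = self._separable_docs()
        cfg = han.HANConfig(
            embed_dim=4, word_hidden=4, sent_hidden=4, attn_dim=4,
            learning_rate=1e-2, epochs=30, patience=30, batch_size=4,
            val_fraction=0.25, max_words_per_sentence=None, seed=0,
        )
        params, _ = han.train_han(docs, labels, cfg)
        # on class-A docs the planted-marker sentence should win attention
        hits = 0
        for doc in docs[:8]:
            out = han.forward(doc, params, cfg)
            marked = max(
                range(len(doc)), key=lambda i: float(np.abs(doc[i]).max())
            )
            hits += int(np.argmax(out.sent_attn) == marked)
        assert hits >= 6

    def test_same_seed_identical_history(self):
        docs, labels = self._separable_docs()
        cfg = han.HANConfig(
            embed_dim=4, word_hidden=2, sent_hidden=2, attn_dim=3,
            learning_rate=1e-2, epochs=5, patience=5, batch_size=4, seed=1,
            max_words_per_sentence=None,
        )
        _, h1 = han.train_han(docs, labels, cfg)
        _, h2 = han.train_han(docs, labels, cfg)
        pd.testing.assert_frame_equal(h1, h2)

    def test_single_class_rejected(self):
        docs, _ = self._separable_docs()
        cfg = _tiny_config(embed_dim=4)
        with pytest.raises(ValueError, match="2 classes"):
            han.train_han(docs, ["A"] * len(docs), cfg)

    def test_grouped_split_keeps_replicates_together(self):
        labels = ["A"] * 6 + ["B"] * 6
        groups = ["a1", "a1", "a1", "a2", "a2", "a2",
                  "b1", "b1", "b1", "b2", "b2", "b2"]
        rng = np.random.default_rng(0)
        train_idx, val_idx = han._grouped_split(labels, groups, 0.5, rng)
        train_groups = {groups[i] for i in train_idx}
        val_groups = {groups[i] for i in val_idx}
        assert not (train_groups & val_groups)
        assert len(val_idx) == 6  # one full origin per class


class TestExtraction:
    def _bundle(self, seed=0):
        rng = np.random.default_rng(seed)
        vocab = {t: i + 1 for i, t in enumerate(["PF1", "PF2", "PF3"])}
        vectors = np.vstack([np.zeros(3), rng.normal(size=(3, 3))])
        embedding = EmbeddingModel(view=1, dim=3, vocabulary=vocab, vectors=vectors)
        cfg = _tiny_config()
        model = han.HANModel(
            config=cfg, params=han.init_params(cfg, rng),
            classes=("A", "B"), view=1,
        )
        doc = Document(
            "sp1", "A", 1,
            (("p1", ("PF1", "PF2")), ("p2", ("PF3",)), ("p3", ("PF2",))),
        )
        return doc, embedding, model

    def test_attention_output_structure(self):
        doc, embedding, model = self._bundle()
        out = han.extract_attention(doc, embedding, model)
        assert out.protein_ids == ("p1", "p2", "p3")
        assert out.sent_attn.sum() == pytest.approx(1.0, abs=1e-6)
        assert len(out.word_attn) == 3

    def test_repeated_calls_identical(self):
        doc, embedding, model = self._bundle()
        a = han.extract_attention(doc, embedding, model)
        b = han.extract_attention(doc, embedding, model)
        np.testing.assert_array_equal(a.sent_attn, b.sent_attn)
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_view_mismatch_rejected(self):
        doc, embedding, model = self._bundle()
        bad = Document("sp1", "A", 2, (("p1", ("MKV",)),))
        with pytest.raises(ValueError, match="view"):
            han.extract_attention(bad, embedding, model)

    def test_order_averaged_extraction_sums_to_one(self):
        doc, embedding, model = self._bundle()
        outs = han.extract_attention_averaged([doc], embedding, model, n_orders=4)
        out = outs["sp1"]
        assert out.sent_attn.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.protein_ids == ("p1", "p2", "p3")


def test_model_save_load_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    cfg = _tiny_config()
    model = han.HANModel(
        config=cfg, params=han.init_params(cfg, rng), classes=("A", "B"), view=1
    )
    path = tmp_path / "model.npz"
    han.save_model(model, path)
    back = han.load_model(path)
    assert back.config == cfg
    assert back.classes == ("A", "B") and back.view == 1
    for k, v in model.params.items():
        np.testing.assert_array_equal(back.params[k].data, v.data)
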