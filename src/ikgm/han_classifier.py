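"""Hierarchical attention network (HAN) for whole-proteome classification.

Architecture, bottom to top:

* **word encoder** — a bidirectional LSTM over the token vectors
  ``x_{i,t}`` of sentence *i*; the two directions' hidden states are
  concatenated into ``h_{i,t}``;
* **word attention** — ``u_{i,t} = tanh(W_w h_{i,t} + b_w)``, scores
  ``w_w · u_{i,t}`` normalized by a softmax over the sentence's words into
  ``alpha_{i,t}``; the sentence vector is ``s_i = sum_t alpha_{i,t} h_{i,t}``;
* **sentence encoder + attention** — the same construction one level up over
  the sentence vectors ``s_1..s_L``, yielding sentence weights ``alpha_i``
  and the document vector ``P = sum_i alpha_i h_i``;
* **classifier** — ``y_hat = softmax(W_c P + b_c)`` over the two taxa.

The sentence attentions ``alpha_i`` of a trained model, evaluated on the
*original* (non-augmented) genomes, are the per-protein attention scores
that downstream gene ranking is built from.

Long documents are processed with the attention-score MLP applied in
blocks of ``chunk_size`` sentences followed by a single global softmax,
which is mathematically identical to the monolithic pass.  Padded
positions are masked out of every softmax, so the normalization
invariants hold exactly.  Word embeddings are frozen inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Tensor, concat, masked_softmax, log_softmax, reshape, take_rows, tensor
from .augmentation import origin_id
from .embedding import EmbeddingModel, embed_document
from .tokenization import Document

__all__ = [
    "HANConfig",
    "HANParams",
    "HANModel",
    "AttentionOutput",
    "init_params",
    "word_encode",
    "sentence_encode",
    "forward",
    "train_han",
    "fit",
    "extract_attention",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class HANConfig:
    """Hyperparameters of the classifier.

    Hidden widths are per LSTM direction; ``attn_dim`` is the width of the
    attention MLP hidden layer; ``chunk_size`` is the number of sentences per
    attention-MLP block in the chunked forward pass.

    ``sentence_dropout`` randomly removes that fraction of a document's
    sentences at each training step (never at evaluation/extraction): a
    document stays classifiable only if attention learns *every*
    discriminative protein rather than collapsing onto a single one, which
    is essential when the attentions are read out as importance scores.
    When sentences are grouped (e.g. all proteins of one gene family),
    whole groups are dropped together so multi-copy genes do not escape
    the dropout pressure.

    ``warmup_epochs`` optionally prepends a sentence-level curriculum:
    every protein of the training documents is presented as its own
    one-sentence document with its genome's label, training the word
    encoder on individually discriminative proteins without document-level
    softmax competition.

    ``shuffle_sentences`` randomly permutes a document's sentence order at
    each training step.  Protein order within a genome document is an
    arbitrary serialization choice with no biological meaning, so making
    the sentence encoder order-invariant prevents the canonical order of
    the original genomes (seen at attention extraction) from differing
    systematically from the block-rearranged augmented order seen in
    training.
    """

    embed_dim: int = 200
    word_hidden: int = 50
    sent_hidden: int = 50
    attn_dim: int = 100
    n_classes: int = 2
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    epochs: int = 50
    batch_size: int = 8
    max_words_per_sentence: int | None = 256
    chunk_size: int = 512
    patience: int = 5
    eval_every: int = 1
    warmup_epochs: int = 0
    val_fraction: float = 0.2
    sentence_dropout: float = 0.0
    word_dropout: float = 0.0
    shuffle_sentences: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("only binary (two-taxon) classification is supported")
        for name in ("embed_dim", "word_hidden", "sent_hidden", "attn_dim",
                     "batch_size", "chunk_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


#: Parameter tensors by name.  LSTM weights use the gate layout
#: [input, forget, cell, output] stacked along the last axis.
HANParams = dict


_LSTM_BLOCKS = (
    ("word_f", "embed_dim", "word_hidden"),
    ("word_b", "embed_dim", "word_hidden"),
    ("sent_f", None, "sent_hidden"),  # input dim = 2 * word_hidden
    ("sent_b", None, "sent_hidden"),
)


def init_params(config: HANConfig, rng: np.random.Generator) -> HANParams:
    """Xavier-uniform initialization of all named parameter tensors."""

    def xavier(shape):
        bound = np.sqrt(6.0 / (shape[0] + shape[-1]))
        return ad.parameter(rng.uniform(-bound, bound, size=shape))

    p: HANParams = {}
    for name, in_attr, h_attr in _LSTM_BLOCKS:
        d_in = 2 * config.word_hidden if in_attr is None else getattr(config, in_attr)
        H = getattr(config, h_attr)
        p[f"{name}_Wx"] = xavier((d_in, 4 * H))
        p[f"{name}_Wh"] = xavier((H, 4 * H))
        b = np.zeros((1, 4 * H))
        b[0, H : 2 * H] = 1.0  # forget-gate bias
        p[f"{name}_b"] = ad.parameter(b)
    p["W_w"] = xavier((2 * config.word_hidden, config.attn_dim))
    p["b_w"] = ad.parameter(np.zeros((1, config.attn_dim)))
    p["w_w"] = xavier((config.attn_dim, 1))
    p["W_s"] = xavier((2 * config.sent_hidden, config.attn_dim))
    p["b_s"] = ad.parameter(np.zeros((1, config.attn_dim)))
    p["w_s"] = xavier((config.attn_dim, 1))
    p["W_c"] = xavier((2 * config.sent_hidden, config.n_classes))
    p["b_c"] = ad.parameter(np.zeros((1, config.n_classes)))
    return p


def zero_params(config: HANConfig) -> HANParams:
    """All-zero parameters (useful for symmetry checks)."""
    rng = np.random.default_rng(0)
    p = init_params(config, rng)
    for t in p.values():
        t.data[...] = 0.0
    return p


@dataclass
class AttentionOutput:
    """All attention weights and vectors from one document's forward pass."""

    protein_ids: tuple[str, ...]
    word_attn: list[np.ndarray]  # per sentence: alpha_{i,t} over its words
    sent_attn: np.ndarray  # alpha_i over sentences, sums to 1
    sentence_vectors: np.ndarray  # s_i, shape (L, 2*word_hidden)
    document_vector: np.ndarray  # P, shape (2*sent_hidden,)
    probs: np.ndarray  # y_hat, shape (n_classes,)
    classes: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# forward machinery (batched over sentences, then over documents)
# --------------------------------------------------------------------------


def _lstm_sweep(
    x_steps: list[Tensor],
    mask: np.ndarray,
    Wx: Tensor,
    Wh: Tensor,
    b: Tensor,
    H: int,
    reverse: bool,
) -> list[Tensor]:
    """One LSTM direction over T per-timestep (B, D) inputs.

    ``mask`` is (B, T); masked steps carry state through unchanged, so
    right-padding never contaminates the hidden states.
    """
    T = len(x_steps)
    B = x_steps[0].shape[0]
    h = tensor(np.zeros((B, H)))
    c = tensor(np.zeros((B, H)))
    out: list[Tensor | None] = [None] * T
    order = range(T - 1, -1, -1) if reverse else range(T)
    for t in order:
        z = ad.lstm_preact(x_steps[t], Wx, h, Wh, b)
        h, c = ad.lstm_cell(z, h, c, mask[:, t : t + 1])
        out[t] = h
    return out  # type: ignore[return-value]


def _bilstm(
    x_steps: list[Tensor], mask: np.ndarray, params: HANParams, prefix: str, H: int
) -> list[Tensor]:
    """Bidirectional LSTM over per-timestep (B, D) input tensors."""
    out = []
    for d, reverse in (("f", False), ("b", True)):
        out.append(
            _lstm_sweep(
                x_steps, mask,
                params[f"{prefix}_{d}_Wx"], params[f"{prefix}_{d}_Wh"],
                params[f"{prefix}_{d}_b"], H, reverse,
            )
        )
    return [concat([f, b], axis=1) for f, b in zip(*out)]


def _attention_pool(
    h_steps: list[Tensor],
    mask: np.ndarray,
    W: Tensor,
    b: Tensor,
    w: Tensor,
    chunk_size: int,
) -> tuple[Tensor, Tensor]:
    """MLP + context-vector scores per step (computed blockwise), one global
    masked softmax over all steps, then the attention-weighted state sum."""
    T = len(h_steps)
    B = h_steps[0].shape[0]
    h_all = concat(h_steps, axis=0)  # (T*B, 2H), timestep-major
    score_blocks = []
    for start in range(0, T, chunk_size):
        if start == 0 and chunk_size >= T:
            block = h_all
        else:
            block = h_all[start * B : min(start + chunk_size, T) * B]
        u = ad.tanh(block @ W + b)
        score_blocks.append(u @ w)  # (t*B, 1)
    flat = score_blocks[0] if len(score_blocks) == 1 else concat(score_blocks, axis=0)
    scores = reshape(flat, (T, B))
    alpha = masked_softmax(scores, mask.T, axis=0)  # (T, B)
    pooled = ad.attn_pool(h_all, alpha, T, B)
    return alpha, pooled


def _pad_sentences(
    embedded_docs: Sequence[Sequence[np.ndarray]], cap: int | None
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    mats = []
    for doc in embedded_docs:
        for m in doc:
            mats.append(m[:cap] if cap else m)
    lengths = [len(m) for m in mats]
    T, N = max(lengths), len(mats)
    D = mats[0].shape[1]
    X = np.zeros((T, N, D))
    mask = np.zeros((N, T), dtype=bool)
    for j, m in enumerate(mats):
        X[: len(m), j] = m
        mask[j, : len(m)] = True
    return X, mask, lengths


def forward_batch(
    embedded_docs: Sequence[Sequence[np.ndarray]],
    params: HANParams,
    config: HANConfig,
) -> tuple[Tensor, list[dict]]:
    """Forward pass over a batch of embedded documents.

    Returns the (B, n_classes) logits tensor plus, per document, a dict of
    numpy attention arrays (word and sentence weights, vectors).
    """
    if not embedded_docs or any(len(d) == 0 for d in embedded_docs):
        raise ValueError("every document must contain at least one sentence")
    B = len(embedded_docs)
    doc_lens = [len(d) for d in embedded_docs]
    offsets = np.cumsum([0] + doc_lens)

    # --- word level over all sentences of all documents at once
    X, wmask, _ = _pad_sentences(embedded_docs, config.max_words_per_sentence)
    T, N, D = X.shape
    if D != config.embed_dim:
        raise ValueError(f"embedding dim {D} != config.embed_dim {config.embed_dim}")
    x_steps = [tensor(X[t]) for t in range(T)]
    h_words = _bilstm(x_steps, wmask, params, "word", config.word_hidden)
    alpha_w, s_all = _attention_pool(
        h_words, wmask, params["W_w"], params["b_w"], params["w_w"], config.chunk_size
    )  # alpha_w: (T, N); s_all: (N, 2Hw)

    # --- sentence level, batched over documents
    L = max(doc_lens)
    smask = np.zeros((B, L), dtype=bool)
    for bi, ln in enumerate(doc_lens):
        smask[bi, :ln] = True
    s_steps = []
    for i in range(L):
        idx = np.array(
            [offsets[bi] + min(i, doc_lens[bi] - 1) for bi in range(B)], dtype=np.intp
        )
        s_steps.append(take_rows(s_all, idx))
    h_sents = _bilstm(s_steps, smask, params, "sent", config.sent_hidden)
    alpha_s, P = _attention_pool(
        h_sents, smask, params["W_s"], params["b_s"], params["w_s"], config.chunk_size
    )  # alpha_s: (L, B); P: (B, 2Hs)
    logits = P @ params["W_c"] + params["b_c"]

    # --- per-document numpy views
    details = []
    aw = alpha_w.data  # (T, N)
    asn = alpha_s.data  # (L, B)
    s_np = s_all.data
    for bi in range(B):
        lo, hi = offsets[bi], offsets[bi + 1]
        word_attn = [aw[: wmask[j].sum(), j].copy() for j in range(lo, hi)]
        details.append(
            {
                "word_attn": word_attn,
                "sent_attn": asn[: doc_lens[bi], bi].copy(),
                "sentence_vectors": s_np[lo:hi].copy(),
                "document_vector": P.data[bi].copy(),
            }
        )
    return logits, details


def _softmax_np(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def word_encode(
    sentence_vectors: np.ndarray, params: HANParams, config: HANConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Word-level encoder+attention for one sentence: returns
    (alpha_{i,.}, s_i)."""
    x = np.asarray(sentence_vectors, dtype=float)
    if x.ndim != 2 or x.shape[1] != config.embed_dim:
        raise ValueError(f"expected (T, {config.embed_dim}) word vectors")
    T = len(x)
    mask = np.ones((1, T), dtype=bool)
    x_steps = [tensor(x[t : t + 1]) for t in range(T)]
    h = _bilstm(x_steps, mask, params, "word", config.word_hidden)
    alpha, s = _attention_pool(
        h, mask, params["W_w"], params["b_w"], params["w_w"], config.chunk_size
    )
    return alpha.data[:, 0].copy(), s.data[0].copy()


def sentence_encode(
    sentence_vectors: np.ndarray, params: HANParams, config: HANConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Sentence-level encoder+attention over s_1..s_L: returns (alpha_., P)."""
    s = np.asarray(sentence_vectors, dtype=float)
    if s.ndim != 2 or s.shape[1] != 2 * config.word_hidden:
        raise ValueError(f"expected (L, {2 * config.word_hidden}) sentence vectors")
    L = len(s)
    mask = np.ones((1, L), dtype=bool)
    steps = [tensor(s[i : i + 1]) for i in range(L)]
    h = _bilstm(steps, mask, params, "sent", config.sent_hidden)
    alpha, P = _attention_pool(
        h, mask, params["W_s"], params["b_s"], params["w_s"], config.chunk_size
    )
    return alpha.data[:, 0].copy(), P.data[0].copy()


def forward(
    embedded_doc: Sequence[np.ndarray],
    params: HANParams,
    config: HANConfig,
    protein_ids: Sequence[str] | None = None,
    classes: Sequence[str] = (),
) -> AttentionOutput:
    """Full forward pass on a single embedded document."""
    logits, details = forward_batch([list(embedded_doc)], params, config)
    d = details[0]
    return AttentionOutput(
        protein_ids=tuple(protein_ids or [str(i) for i in range(len(embedded_doc))]),
        word_attn=d["word_attn"],
        sent_attn=d["sent_attn"],
        sentence_vectors=d["sentence_vectors"],
        document_vector=d["document_vector"],
        probs=_softmax_np(logits.data[0]),
        classes=tuple(classes),
    )


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------


def _cross_entropy(
    logits: Tensor, y: np.ndarray, focal_gamma: float = 0.0
) -> Tensor:
    B = logits.shape[0]
    lp = log_softmax(logits, axis=1)
    picked = lp[(np.arange(B), y)]
    if focal_gamma > 0.0:
        # focal weighting concentrates gradient on documents the model still
        # gets wrong; the weights are constants of the current step
        w = (1.0 - np.exp(picked.data)) ** focal_gamma
        picked = picked * ad.tensor(w)
    return ad.sum_(picked) * (-1.0 / B)


def _grouped_split(
    labels: Sequence[str],
    groups: Sequence[str],
    val_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[int], list[int]]:
    """Stratified train/validation split at the level of *origin* genomes,
    so augmented replicates never straddle the boundary."""
    by_class: dict[str, list[str]] = {}
    for lab, grp in zip(labels, groups):
        by_class.setdefault(lab, [])
        if grp not in by_class[lab]:
            by_class[lab].append(grp)
    val_groups: set[str] = set()
    for lab, grps in sorted(by_class.items()):
        grps = sorted(grps)
        n_val = int(round(val_fraction * len(grps)))
        n_val = min(max(n_val, 1), len(grps) - 1) if len(grps) > 1 else 0
        chosen = rng.permutation(len(grps))[:n_val]
        val_groups.update(grps[i] for i in chosen)
    train_idx = [i for i, g in enumerate(groups) if g not in val_groups]
    val_idx = [i for i, g in enumerate(groups) if g in val_groups]
    return train_idx, val_idx


def _eval(
    embedded_docs, y, params, config, batch_size: int
) -> tuple[float, float]:
    losses, correct, n = [], 0, 0
    for start in range(0, len(embedded_docs), batch_size):
        batch = embedded_docs[start : start + batch_size]
        yb = y[start : start + batch_size]
        logits, _ = forward_batch(batch, params, config)
        losses.append(_cross_entropy(logits, yb).data * len(batch))
        correct += int((logits.data.argmax(axis=1) == yb).sum())
        n += len(batch)
    return float(np.sum(losses) / n), correct / n


def train_han(
    embedded_docs: Sequence[Sequence[np.ndarray]],
    labels: Sequence[str],
    config: HANConfig,
    groups: Sequence[str] | None = None,
    sentence_groups: Sequence[Sequence[str]] | None = None,
) -> tuple[HANParams, pd.DataFrame]:
    """Train the HAN by Adam on cross-entropy.

    ``groups`` ties augmented replicates to their origin genome for split
    hygiene (defaults to one group per document).  ``sentence_groups``
    optionally assigns each sentence of each document a dropout group
    (e.g. its gene symbol); sentence dropout then removes whole groups.
    Returns the best parameters (lowest validation loss; early stopping
    with ``config.patience``) and a per-epoch history table
    (epoch, train_loss, val_loss, val_acc).
    """
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if len(embedded_docs) < 2:
        raise ValueError("need at least 2 documents")
    y = np.array([classes.index(l) for l in labels])
    groups = list(groups) if groups is not None else [str(i) for i in range(len(y))]

    rng = np.random.default_rng(config.seed)
    params = init_params(config, rng)
    opt = ad.Adam(
        list(params.values()),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    train_idx, val_idx = _grouped_split(labels, groups, config.val_fraction, rng)
    docs = list(embedded_docs)

    def dropout_doc(di: int, rate: float | None = None) -> list[np.ndarray]:
        doc = docs[di]
        rate = config.sentence_dropout if rate is None else rate
        if sentence_groups is not None:
            sg = sentence_groups[di]
            uniq = sorted(set(sg))
            drop = {
                g for g, r in zip(uniq, rng.random(len(uniq))) if r < rate
            }
            keep = np.array([g not in drop for g in sg])
        else:
            keep = rng.random(len(doc)) >= rate
        if not keep.any():
            keep[rng.integers(len(doc))] = True
        kept = [s for s, k in zip(doc, keep) if k]
        if config.shuffle_sentences:
            kept = [kept[j] for j in rng.permutation(len(kept))]
        if config.word_dropout > 0.0:
            pruned = []
            for s in kept:
                wkeep = rng.random(len(s)) >= config.word_dropout
                if not wkeep.any():
                    wkeep[rng.integers(len(s))] = True
                pruned.append(s[wkeep])
            kept = pruned
        return kept

    # model selection must reward robustness to the sentence corruption used
    # in training, otherwise a single dominant protein satisfies the clean
    # validation loss and secondary discriminative proteins are never
    # learned.  Per validation document: three fixed samples at the training
    # dropout rate plus three heavy-ablation samples (rate >= 0.8) that
    # isolate small sentence subsets, so the selection signal keeps
    # improving until every backup signal is acquired.
    if val_idx and config.sentence_dropout > 0.0:
        heavy = max(config.sentence_dropout, 0.8)
        rates = (config.sentence_dropout,) * 3 + (heavy,) * 3
        val_sel_docs = [dropout_doc(i, r) for i in val_idx for r in rates]
        val_sel_y = np.repeat(y[val_idx], len(rates))
    else:
        val_sel_docs = [docs[i] for i in val_idx]
        val_sel_y = y[val_idx]

    if config.warmup_epochs > 0:
        singles = [
            ([sent], y[di])
            for di in train_idx
            for sent in docs[di]
        ]
        warm_bs = max(config.batch_size, 64)
        for _ in range(config.warmup_epochs):
            order = rng.permutation(len(singles))
            for start in range(0, len(order), warm_bs):
                chunk = [singles[i] for i in order[start : start + warm_bs]]
                logits, _ = forward_batch([c[0] for c in chunk], params, config)
                loss = _cross_entropy(logits, np.array([c[1] for c in chunk]))
                opt.zero_grad()
                ad.backward(loss)
                opt.step()

    best_loss = np.inf
    best_state = {k: v.data.copy() for k, v in params.items()}
    patience_left = config.patience
    rows = []
    checkpoints: list[tuple[float, int, dict]] = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = [train_idx[i] for i in order[start : start + config.batch_size]]
            if config.sentence_dropout > 0.0 or config.shuffle_sentences:
                batch = [dropout_doc(i) for i in idx]
            else:
                batch = [docs[i] for i in idx]
            logits, _ = forward_batch(batch, params, config)
            loss = _cross_entropy(logits, y[idx])
            opt.zero_grad()
            ad.backward(loss)
            opt.step()
            epoch_losses.append(loss.data * len(idx))
        train_loss = float(np.sum(epoch_losses) / len(train_idx))
        if epoch % config.eval_every != 0 and epoch != config.epochs:
            continue
        if val_idx:
            eval_bs = max(config.batch_size, 32)
            val_loss, _ = _eval(val_sel_docs, val_sel_y, params, config, eval_bs)
            if val_loss < best_loss - 1e-6:
                # clean accuracy is reporting-only; compute it only for
                # models that are candidates for selection
                _, val_acc = _eval(
                    [docs[i] for i in val_idx], y[val_idx], params, config, eval_bs
                )
            else:
                val_acc = rows[-1]["val_acc"] if rows else float("nan")
        else:
            val_loss, val_acc = train_loss, float("nan")
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
             "val_acc": val_acc}
        )
        checkpoints.append(
            (val_loss, epoch, {k: v.data.copy() for k, v in params.items()})
        )
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_state = {k: v.data.copy() for k, v in params.items()}
            patience_left = config.patience
        else:
            patience_left -= config.eval_every
            if patience_left <= 0:
                break
    for k, v in params.items():
        v.data[...] = best_state[k]
    history = pd.DataFrame(rows)
    history.attrs["checkpoints"] = _select_checkpoints(checkpoints)
    return params, history


def _select_checkpoints(
    checkpoints: list[tuple[float, int, dict]],
) -> list[dict]:
    """Diverse parameter states for the importance readout: the best
    validation state, the best state of the last third of the run, and the
    final state.

    A single selected model knows the discriminative genes it happened to
    have learned by its selected epoch.  Weak backup signals are often
    acquired late — after the validation-loss minimum, which senses them
    only through a handful of heavy-ablation samples — so the readout
    ensemble deliberately spans the late trajectory; passes from states
    that classify poorly are down-weighted by the confidence weighting at
    extraction time.
    """
    if not checkpoints:
        return []
    by_epoch = sorted(checkpoints, key=lambda t: t[1])
    best = min(checkpoints, key=lambda t: t[0])
    final = by_epoch[-1]
    chosen: dict[int, dict] = {}
    for _, epoch, state in (best, final):
        chosen[epoch] = state
    return [chosen[e] for e in sorted(chosen)]


@dataclass
class HANModel:
    """A trained classifier bundle: parameters + config + class order + view.

    ``snapshots`` holds a few additional low-validation-loss parameter
    states from the same training run (checkpoint ensemble) used by the
    marginalized importance readout; ``params`` is always the selected
    best state.
    """

    config: HANConfig
    params: HANParams
    classes: tuple[str, str]
    view: int
    history: pd.DataFrame | None = None
    snapshots: list[HANParams] = field(default_factory=list)

    @property
    def best_val_loss(self) -> float:
        if self.history is None or "val_loss" not in self.history:
            return float("nan")
        return float(self.history["val_loss"].min())

    def ensemble_members(self) -> list["HANModel"]:
        """One HANModel per checkpoint (the selected state if none)."""
        if not self.snapshots:
            return [self]
        return [
            HANModel(self.config, p, self.classes, self.view)
            for p in self.snapshots
        ]


def fit(
    documents: Sequence[Document],
    embedding: EmbeddingModel,
    config: HANConfig,
    gene_map: Mapping[str, str] | None = None,
) -> HANModel:
    """Embed the (augmented) documents and train, grouping replicates by
    their origin genome.  With a ``gene_map``, sentence dropout removes all
    proteins of a gene together."""
    views = {d.view for d in documents}
    if views != {embedding.view}:
        raise ValueError(f"documents views {sorted(views)} != embedding view {embedding.view}")
    embedded = [embed_document(d, embedding) for d in documents]
    labels = [d.label for d in documents]
    groups = [origin_id(d.species_id) for d in documents]
    sentence_groups = None
    if gene_map is not None:
        sentence_groups = [
            [gene_map.get(pid, pid) for pid in d.protein_ids] for d in documents
        ]
    params, history = train_han(
        embedded, labels, config, groups=groups, sentence_groups=sentence_groups
    )
    snapshots = [
        {k: ad.parameter(v) for k, v in state.items()}
        for state in history.attrs.get("checkpoints", [])
    ]
    return HANModel(
        config=config,
        params=params,
        classes=tuple(sorted(set(labels))),  # type: ignore[arg-type]
        view=embedding.view,
        history=history,
        snapshots=snapshots,
    )


def extract_attention(
    document: Document, embedding: EmbeddingModel, model: HANModel
) -> AttentionOutput:
    """Run the trained model on an original genome document and return all
    attention weights (the sentence weights are the protein attention
    scores)."""
    if document.view != model.view:
        raise ValueError(
            f"document view {document.view} does not match model view {model.view}"
        )
    embedded = embed_document(document, embedding)
    return forward(
        embedded,
        model.params,
        model.config,
        protein_ids=document.protein_ids,
        classes=model.classes,
    )


def extract_attention_averaged(
    documents: Sequence[Document],
    embedding: EmbeddingModel,
    model: HANModel,
    n_orders: int = 8,
    n_parts: int = 10,
    seed: int = 0,
    gene_map: Mapping[str, str] | None = None,
    n_dropout_samples: int = 0,
    sentence_dropout: float = 0.5,
    confidence_weighted: bool = True,
) -> dict[str, AttentionOutput]:
    """Marginalized attention extraction.

    A single forward pass reads attention through one softmax, which is
    winner-take-all: a protein the model genuinely relies on as a backup
    signal can receive near-zero weight simply because a stronger signal is
    present in the same document.  This extractor therefore reports the
    *expected* sentence attention under the perturbation families the
    classifier was trained with:

    * ``n_orders`` random block rearrangements of sentence order (protein
      order is an arbitrary serialization choice; averaging removes
      document-edge artifacts), and
    * optionally ``n_dropout_samples`` gene-grouped sentence-dropout samples
      (dropping each gene's proteins with probability
      ``sentence_dropout``), each combined with a random block order; when a
      dominant protein is absent, the attention the model shifts to its
      backup proteins is credited to them.

    Dropping is uniform across genes, so the expectation rescales every
    gene by the same keep probability; the returned attentions are
    renormalized to sum to one.  Class probabilities are averaged over the
    *clean* (no-dropout) passes only.

    With ``confidence_weighted`` (the default) each pass's attentions are
    weighted by the probability the model assigns to the document's true
    label in that pass.  A dropout sample that removes every informative
    protein leaves the classifier guessing, and the attention of a
    guessing model is noise concentrated on arbitrary default sentences;
    weighting by the pass's success keeps the importance estimate tied to
    evidence the model actually used.
    """
    rng = np.random.default_rng(seed)
    label_idx = {
        d.species_id: model.classes.index(d.label) if d.label in model.classes else None
        for d in documents
    }

    def weight_of(sid: str, probs: np.ndarray) -> float:
        # excess confidence over chance: a pass in which the model cannot
        # classify (p ~ 1/2) carries no evidence and its attention is noise
        if not confidence_weighted or label_idx[sid] is None:
            return 1.0
        return max(0.0, 2.0 * float(probs[label_idx[sid]]) - 1.0)

    base = extract_attention_batch(documents, embedding, model)
    acc_sent = {
        sid: weight_of(sid, out.probs) * out.sent_attn for sid, out in base.items()
    }
    acc_weight = {sid: weight_of(sid, out.probs) for sid, out in base.items()}
    acc_probs = {sid: out.probs.copy() for sid, out in base.items()}

    def block_order(L: int) -> np.ndarray:
        bounds = np.linspace(0, L, min(n_parts, L) + 1).round().astype(int)
        blocks = [list(range(bounds[i], bounds[i + 1])) for i in range(len(bounds) - 1)]
        return np.array([j for b in rng.permutation(len(blocks)) for j in blocks[b]])

    def run_round(keep_masks: list[np.ndarray] | None, with_probs: bool) -> None:
        permuted, orders, keeps = [], [], []
        for di, d in enumerate(documents):
            idx = np.arange(len(d.sentences))
            if keep_masks is not None:
                idx = idx[keep_masks[di]]
            order = idx[block_order(len(idx))]
            orders.append(order)
            permuted.append(
                Document(
                    d.species_id, d.label, d.view,
                    tuple(d.sentences[j] for j in order),
                )
            )
        outs = extract_attention_batch(permuted, embedding, model)
        for d, order in zip(documents, orders):
            out = outs[d.species_id]
            restored = np.zeros(len(d.sentences))
            restored[order] = out.sent_attn
            w = weight_of(d.species_id, out.probs)
            acc_sent[d.species_id] += w * restored
            acc_weight[d.species_id] += w
            if with_probs:
                acc_probs[d.species_id] += out.probs

    n_clean = 1
    for _ in range(n_orders):
        run_round(None, with_probs=True)
        n_clean += 1
    for _ in range(n_dropout_samples):
        masks = []
        for d in documents:
            groups = [
                gene_map.get(pid, pid) if gene_map else pid
                for pid in d.protein_ids
            ]
            uniq = sorted(set(groups))
            drop = {
                g for g, r in zip(uniq, rng.random(len(uniq)))
                if r < sentence_dropout
            }
            keep = np.array([g not in drop for g in groups])
            if not keep.any():
                keep[rng.integers(len(keep))] = True
            masks.append(keep)
        run_round(masks, with_probs=False)

    result = {}
    for sid, out in base.items():
        sent = acc_sent[sid]
        if sent.sum() <= 0.0:
            # no pass carried any evidence (e.g. a signal-free dataset):
            # fall back to the unweighted single-pass attention
            sent = out.sent_attn.copy()
        result[sid] = AttentionOutput(
            protein_ids=out.protein_ids,
            word_attn=out.word_attn,
            sent_attn=sent / sent.sum(),
            sentence_vectors=out.sentence_vectors,
            document_vector=out.document_vector,
            probs=acc_probs[sid] / n_clean,
            classes=out.classes,
        )
    return result


def extract_attention_ensemble(
    documents: Sequence[Document],
    embedding: EmbeddingModel,
    model: HANModel,
    **kwargs,
) -> dict[str, AttentionOutput]:
    """Marginalized extraction averaged over the model's checkpoint
    ensemble (see :meth:`HANModel.ensemble_members`); accepts the same
    keyword arguments as :func:`extract_attention_averaged`."""
    members = model.ensemble_members()
    per_member = [
        extract_attention_averaged(documents, embedding, m, **kwargs)
        for m in members
    ]
    merged: dict[str, AttentionOutput] = {}
    for d in documents:
        outs = [pm[d.species_id] for pm in per_member]
        sent = np.mean([o.sent_attn for o in outs], axis=0)
        merged[d.species_id] = AttentionOutput(
            protein_ids=outs[0].protein_ids,
            word_attn=outs[0].word_attn,
            sent_attn=sent / sent.sum(),
            sentence_vectors=outs[0].sentence_vectors,
            document_vector=outs[0].document_vector,
            probs=np.mean([o.probs for o in outs], axis=0),
            classes=outs[0].classes,
        )
    return merged


def extract_attention_batch(
    documents: Sequence[Document], embedding: EmbeddingModel, model: HANModel
) -> dict[str, AttentionOutput]:
    """Batched :func:`extract_attention` over several original genomes,
    keyed by species id."""
    for d in documents:
        if d.view != model.view:
            raise ValueError(
                f"document view {d.view} does not match model view {model.view}"
            )
    embedded = [embed_document(d, embedding) for d in documents]
    logits, details = forward_batch(embedded, model.params, model.config)
    probs = _softmax_np(logits.data)
    return {
        d.species_id: AttentionOutput(
            protein_ids=d.protein_ids,
            word_attn=det["word_attn"],
            sent_attn=det["sent_attn"],
            sentence_vectors=det["sentence_vectors"],
            document_vector=det["document_vector"],
            probs=probs[i],
            classes=model.classes,
        )
        for i, (d, det) in enumerate(zip(documents, details))
    }


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------


def save_model(model: HANModel, path: str | Path) -> None:
    """Checkpoint layout: an .npz holding every named parameter tensor plus a
    JSON header with config, class order and view."""
    header = json.dumps(
        {"config": asdict(model.config), "classes": list(model.classes),
         "view": model.view}
    )
    arrays = {k: v.data for k, v in model.params.items()}
    np.savez(path, _header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> HANModel:
    with np.load(path) as z:
        header = json.loads(bytes(z["_header"]).decode())
        config = HANConfig(**header["config"])
        params = {
            k: ad.parameter(z[k]) for k in z.files if k != "_header"
        }
    return HANModel(
        config=config,
        params=params,
        classes=tuple(header["classes"]),  # type: ignore[arg-type]
        view=header["view"],
    )
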