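"""Skip-gram word embeddings for biological tokens, plus diagnostics.

Tokens (domain names or variant-kmer peptides) are embedded with the
classic skip-gram / negative-sampling objective: for each (center, context)
pair drawn from a sliding window over a sentence, the dot product of the
center's input vector and the context's output vector is pushed up, while
dot products with ``negative`` randomly drawn tokens (unigram^0.75 noise
distribution) are pushed down.  Training is plain SGD with a linearly
decaying learning rate, single-threaded and fully deterministic under a
fixed seed.

The resulting vectors are frozen inputs to the classifier: a document is
encoded by replacing every token with its vector (out-of-vocabulary tokens
map to a reserved all-zero UNK vector, so attention stays computable for
every word).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tokenization import Document

__all__ = [
    "EmbeddingModel",
    "train_skipgram",
    "embed_document",
    "embedding_diagnostics",
    "save_embedding",
    "load_embedding",
]

UNK_INDEX = 0


@dataclass
class EmbeddingModel:
    """Trained token vectors for one word-hierarchy view.

    ``vectors[0]`` is the reserved UNK row and is identically zero; real
    tokens occupy rows 1..V in ``vocabulary`` order.
    """

    view: int
    dim: int
    vocabulary: dict[str, int]
    vectors: np.ndarray
    min_count: int = 2
    window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vectors.shape != (len(self.vocabulary) + 1, self.dim):
            raise ValueError("vectors shape inconsistent with vocabulary/dim")

    def index_of(self, token: str) -> int:
        return self.vocabulary.get(token, UNK_INDEX)

    def vector_of(self, token: str) -> np.ndarray:
        return self.vectors[self.index_of(token)]


def _scatter_add(W: np.ndarray, idx: np.ndarray, grads: np.ndarray) -> None:
    # duplicate-safe row scatter-add via sort + segment reduction
    order = np.argsort(idx, kind="stable")
    idx_s = idx[order]
    uniq, starts = np.unique(idx_s, return_index=True)
    W[uniq] += np.add.reduceat(grads[order], starts, axis=0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_skipgram(
    documents: Sequence[Document],
    dim: int = 200,
    window: int = 5,
    min_count: int = 2,
    negative: int = 5,
    epochs: int = 5,
    seed: int = 0,
    batch_size: int = 8192,
    lr: float = 0.025,
) -> EmbeddingModel:
    """Train skip-gram vectors on the tokenized (augmented) corpus.

    Uses dynamic window shrinking (effective window ~ Uniform{1..window} per
    center, as in word2vec) and ``negative`` noise samples per pair.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    views = {d.view for d in documents}
    if len(views) != 1:
        raise ValueError(f"documents mix views {sorted(views)}")
    view = views.pop()

    sentences = [tokens for d in documents for tokens in d.token_lists()]
    if not sentences:
        raise ValueError("no sentences to train on")
    counts: dict[str, int] = {}
    for s in sentences:
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    vocab = {
        t: i + 1
        for i, t in enumerate(sorted(t for t, c in counts.items() if c >= min_count))
    }
    if not vocab:
        raise ValueError(f"empty vocabulary after min_count={min_count} filtering")
    V = len(vocab)

    # corpus as index streams, OOV tokens dropped before windowing
    encoded = [
        np.array([vocab[t] for t in s if t in vocab], dtype=np.int64)
        for s in sentences
    ]
    encoded = [e for e in encoded if len(e) >= 2]

    rng = np.random.default_rng(seed)
    W = (rng.random((V + 1, dim)) - 0.5) / dim  # input (center) vectors
    C = np.zeros((V + 1, dim))  # output (context) vectors
    W[UNK_INDEX] = 0.0

    # noise distribution: unigram^0.75 over retained vocab
    freq = np.zeros(V + 1)
    for t, i in vocab.items():
        freq[i] = counts[t]
    noise = freq**0.75
    noise[UNK_INDEX] = 0.0
    noise_cdf = np.cumsum(noise / noise.sum())

    # pairs are rebuilt each epoch with fresh dynamic windows; the lr decay
    # horizon uses the expected pair count (2 * E[b] per center per side)
    step = 0
    approx_pairs = sum(len(e) for e in encoded) * (window + 1)
    # keep a sensible SGD step count even on tiny corpora
    batch_size = int(min(batch_size, max(16, approx_pairs // 32)))
    total_steps = epochs * max(1, -(-approx_pairs // batch_size))

    for epoch in range(epochs):
        centers_l: list[np.ndarray] = []
        contexts_l: list[np.ndarray] = []
        for e in encoded:
            n = len(e)
            b = rng.integers(1, window + 1, size=n)
            for off in range(1, min(window, n - 1) + 1):
                sel = np.nonzero(b[: n - off] >= off)[0]
                if len(sel):
                    centers_l.append(e[sel])
                    contexts_l.append(e[sel + off])
                    centers_l.append(e[sel + off])
                    contexts_l.append(e[sel])
        centers = np.concatenate(centers_l)
        contexts = np.concatenate(contexts_l)
        perm = rng.permutation(len(centers))
        centers, contexts = centers[perm], contexts[perm]

        for start in range(0, len(centers), batch_size):
            c = centers[start : start + batch_size]
            o = contexts[start : start + batch_size]
            B = len(c)
            negs = np.searchsorted(
                noise_cdf, rng.random((B, negative)), side="right"
            ) + 0
            cur_lr = lr * max(1e-4 / lr, 1.0 - step / total_steps)
            step += 1

            v = W[c]  # (B, D)
            u_pos = C[o]  # (B, D)
            u_neg = C[negs]  # (B, K, D)
            g_pos = _sigmoid(np.einsum("bd,bd->b", v, u_pos)) - 1.0  # (B,)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", v, u_neg))  # (B, K)
            # a noise draw that collides with the true context would cancel
            # the positive update (relevant for small vocabularies)
            g_neg *= negs != o[:, None]

            grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            grad_upos = g_pos[:, None] * v
            grad_uneg = g_neg[:, :, None] * v[:, None, :]

            _scatter_add(W, c, -cur_lr * grad_v)
            _scatter_add(C, o, -cur_lr * grad_upos)
            _scatter_add(
                C, negs.ravel(), -cur_lr * grad_uneg.reshape(B * negative, dim)
            )

    W[UNK_INDEX] = 0.0
    # guard the invariant that every retained token has a non-zero vector
    norms = np.linalg.norm(W[1:], axis=1)
    if np.any(norms == 0) or not np.all(np.isfinite(W)):
        raise RuntimeError("skip-gram training produced zero or non-finite vectors")
    return EmbeddingModel(
        view=view,
        dim=dim,
        vocabulary=vocab,
        vectors=W,
        min_count=min_count,
        window=window,
        seed=seed,
    )


def embed_document(document: Document, model: EmbeddingModel) -> list[np.ndarray]:
    """Per sentence, the (n_tokens, dim) matrix of token vectors in order;
    out-of-vocabulary tokens become zero rows."""
    if document.view != model.view:
        raise ValueError(
            f"document view {document.view} does not match model view {model.view}"
        )
    matrices = []
    for pid, tokens in document.sentences:
        idx = np.array([model.index_of(t) for t in tokens], dtype=np.int64)
        if np.all(idx == UNK_INDEX):
            warnings.warn(f"sentence {pid!r}: every token is out of vocabulary")
        matrices.append(model.vectors[idx])
    return matrices


def embedding_diagnostics(
    model: EmbeddingModel, K: int = 3, seed: int = 0
) -> pd.DataFrame:
    """K-means cluster label and 2-D PCA projection per vocabulary token.

    Returns a DataFrame with columns (token, cluster, pc1, pc2); useful for
    eyeballing whether the two taxa's tokens separate in embedding space.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    V = len(model.vocabulary)
    if V < K:
        raise ValueError(f"vocabulary size {V} < K={K}")
    tokens = sorted(model.vocabulary, key=model.vocabulary.get)
    X = model.vectors[1:]
    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(X)
    n_comp = min(2, X.shape[1], X.shape[0])
    proj = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    if n_comp < 2:
        proj = np.column_stack([proj, np.zeros(len(X))])
    return pd.DataFrame(
        {
            "token": tokens,
            "cluster": km.labels_,
            "pc1": proj[:, 0],
            "pc2": proj[:, 1],
        }
    )


def save_embedding(model: EmbeddingModel, path: str | Path) -> None:
    """Persist in word2vec text format with a metadata comment line."""
    tokens = sorted(model.vocabulary, key=model.vocabulary.get)
    with open(path, "w") as fh:
        fh.write(f"{len(tokens)} {model.dim}\n")
        fh.write(
            f"#meta view={model.view} min_count={model.min_count} "
            f"window={model.window} seed={model.seed}\n"
        )
        for t in tokens:
            vec = " ".join(repr(float(x)) for x in model.vectors[model.vocabulary[t]])
            fh.write(f"{t} {vec}\n")


def load_embedding(path: str | Path) -> EmbeddingModel:
    with open(path) as fh:
        n, dim = map(int, fh.readline().split())
        meta = dict(
            kv.split("=") for kv in fh.readline().strip().lstrip("# ").split()[1:]
        )
        vocab: dict[str, int] = {}
        vectors = np.zeros((n + 1, dim))
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            vocab[parts[0]] = i + 1
            vectors[i + 1] = [float(x) for x in parts[1 : dim + 1]]
    return EmbeddingModel(
        view=int(meta["view"]),
        dim=dim,
        vocabulary=vocab,
        vectors=vectors,
        min_count=int(meta["min_count"]),
        window=int(meta["window"]),
        seed=int(meta["seed"]),
    )
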