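"""Distributed-memory paragraph vectors (Doc2Vec-style document embeddings).

A document vector is learned jointly with word vectors by predicting each
word from the average of the document vector and the surrounding context
word vectors, optimized with negative sampling.  The implementation is
self-contained numpy: deterministic given the seed, single-threaded, with
mini-batched updates for speed.

New documents are embedded by gradient steps on a fresh document vector with
the trained word and output weights frozen, which is also how training and
test folds obtain their feature vectors in the prediction pipeline (the
model itself is only ever fitted on the training fold).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


@dataclass
class ParagraphVectorModel:
    """Trained embedding model: vocabulary, word/output weights, doc vectors."""

    d: int
    seed: int
    epochs: int
    window: int
    min_count: int
    negative: int
    vocab: dict[str, int]
    word_vectors: np.ndarray  # (m, d)
    output_weights: np.ndarray  # (m, d)
    doc_vectors: np.ndarray  # (n_train_docs, d)
    noise_probs: np.ndarray  # (m,) unigram^0.75 negative-sampling distribution
    alpha: float = 0.025
    min_alpha: float = 1e-4

    def sidecar(self) -> dict:
        """JSON-serializable training metadata."""
        return {
            "d": self.d,
            "seed": self.seed,
            "epochs": self.epochs,
            "window": self.window,
            "min_count": self.min_count,
            "negative": self.negative,
            "vocab_size": len(self.vocab),
            "n_train_docs": len(self.doc_vectors),
        }

    def write_sidecar(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.sidecar(), indent=2) + "\n")


def _positions(
    docs_ids: list[list[int]], window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten (doc, center, padded context) triples for every token position."""
    centers, doc_idx, contexts = [], [], []
    width = 2 * window
    for j, ids in enumerate(docs_ids):
        for t, center in enumerate(ids):
            ctx = ids[max(0, t - window) : t] + ids[t + 1 : t + 1 + window]
            centers.append(center)
            doc_idx.append(j)
            contexts.append(ctx + [-1] * (width - len(ctx)))
    centers_a = np.array(centers, dtype=np.int64)
    doc_a = np.array(doc_idx, dtype=np.int64)
    ctx_a = np.array(contexts, dtype=np.int64).reshape(len(centers), width)
    n_ctx = (ctx_a >= 0).sum(axis=1)
    return centers_a, doc_a, ctx_a, n_ctx


def _scatter_add(target: np.ndarray, idx: np.ndarray, updates: np.ndarray) -> None:
    """Grouped row accumulation (duplicate-safe), faster than ``np.add.at``."""
    idx = idx.ravel()
    updates = updates.reshape(len(idx), -1)
    order = np.argsort(idx, kind="stable")
    sorted_idx = idx[order]
    uniq, starts = np.unique(sorted_idx, return_index=True)
    target[uniq] += np.add.reduceat(updates[order], starts, axis=0)


def _batch_update(
    h: np.ndarray,
    rows: np.ndarray,
    labels: np.ndarray,
    output_weights: np.ndarray,
    lr: float,
) -> np.ndarray:
    """One negative-sampling step; updates output weights, returns grad wrt h."""
    U = output_weights[rows]  # (B, 1+neg, d)
    scores = np.einsum("bkd,bd->bk", U, h)
    g = (_sigmoid(scores) - labels) * lr  # (B, 1+neg)
    grad_h = np.einsum("bk,bkd->bd", g, U)
    _scatter_add(output_weights, rows, -g[:, :, None] * h[:, None, :])
    return grad_h


def train_doc_embedding(
    training_descriptions: list[list[str]],
    d: int = 100,
    seed: int = 0,
    epochs: int = 20,
    window: int = 5,
    min_count: int = 2,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
    batch_size: int = 512,
) -> ParagraphVectorModel:
    """Train the paragraph-vector model on the training fold only.

    Requires at least two non-empty documents.  The vocabulary keeps tokens
    with corpus count >= ``min_count`` (ordered by count, ties lexicographic);
    the learning rate decays linearly from ``alpha`` to ``min_alpha``.
    """
    n_nonempty = sum(1 for doc in training_descriptions if doc)
    if n_nonempty < 2:
        raise ValueError(
            "train_doc_embedding requires at least 2 non-empty documents "
            f"(got {n_nonempty})"
        )
    counts: Counter = Counter()
    for doc in training_descriptions:
        counts.update(doc)
    vocab_tokens = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    if not vocab_tokens:
        raise ValueError(
            f"no token reaches min_count={min_count}; corpus too small or too sparse"
        )
    vocab = {t: i for i, t in enumerate(vocab_tokens)}
    docs_ids = [[vocab[t] for t in doc if t in vocab] for doc in training_descriptions]

    m = len(vocab)
    n_docs = len(training_descriptions)
    rng = np.random.default_rng(seed)
    word_vectors = rng.uniform(-0.5 / d, 0.5 / d, size=(m, d))
    doc_vectors = rng.uniform(-0.5 / d, 0.5 / d, size=(n_docs, d))
    output_weights = np.zeros((m, d))

    noise = np.array([counts[t] for t in vocab_tokens], dtype=float) ** 0.75
    noise /= noise.sum()

    centers, doc_idx, ctx, n_ctx = _positions(docs_ids, window)
    n_pos = len(centers)
    if n_pos == 0:
        raise ValueError("no trainable positions after vocabulary filtering")

    total_batches = max(1, epochs * ((n_pos + batch_size - 1) // batch_size))
    batch_no = 0
    for _ in range(epochs):
        order = rng.permutation(n_pos)
        for start in range(0, n_pos, batch_size):
            sel = order[start : start + batch_size]
            lr = alpha - (alpha - min_alpha) * (batch_no / total_batches)
            batch_no += 1
            B = len(sel)
            c_ids = ctx[sel]
            mask = c_ids >= 0
            c_safe = np.where(mask, c_ids, 0)
            denom = (1.0 + n_ctx[sel])[:, None]
            h = (
                doc_vectors[doc_idx[sel]]
                + (word_vectors[c_safe] * mask[:, :, None]).sum(axis=1)
            ) / denom
            negs = rng.choice(m, size=(B, negative), p=noise)
            rows = np.concatenate([centers[sel][:, None], negs], axis=1)
            labels = np.zeros((B, 1 + negative))
            labels[:, 0] = 1.0
            grad_h = _batch_update(h, rows, labels, output_weights, lr)
            share = grad_h / denom
            _scatter_add(doc_vectors, doc_idx[sel], -share)
            _scatter_add(word_vectors, c_safe, -(share[:, None, :] * mask[:, :, None]))

    return ParagraphVectorModel(
        d=d,
        seed=seed,
        epochs=epochs,
        window=window,
        min_count=min_count,
        negative=negative,
        vocab=vocab,
        word_vectors=word_vectors,
        output_weights=output_weights,
        doc_vectors=doc_vectors,
        noise_probs=noise,
        alpha=alpha,
        min_alpha=min_alpha,
    )


def infer_embedding(
    model: ParagraphVectorModel,
    description: list[str],
    epochs: int | None = None,
) -> np.ndarray:
    """Embed one document with word/output weights frozen.

    The document vector starts at zero and takes full-batch gradient steps on
    the document's own positions; negatives are drawn from a fresh generator
    seeded with the model seed, so repeated inference of the same document is
    bit-identical.  Empty or fully out-of-vocabulary documents map to the
    zero vector by convention.
    """
    epochs = model.epochs if epochs is None else epochs
    ids = [model.vocab[t] for t in description if t in model.vocab]
    if not ids:
        return np.zeros(model.d)
    centers, _, ctx, n_ctx = _positions([ids], model.window)
    mask = ctx >= 0
    c_safe = np.where(mask, ctx, 0)
    ctx_sum = (model.word_vectors[c_safe] * mask[:, :, None]).sum(axis=1)
    denom = (1.0 + n_ctx)[:, None]
    m = len(model.vocab)
    rng = np.random.default_rng(model.seed)
    vec = np.zeros(model.d)
    labels = np.zeros((len(centers), 1 + model.negative))
    labels[:, 0] = 1.0
    for e in range(epochs):
        lr = model.alpha - (model.alpha - model.min_alpha) * (e / max(1, epochs))
        h = (vec[None, :] + ctx_sum) / denom
        negs = rng.choice(m, size=(len(centers), model.negative), p=model.noise_probs)
        rows = np.concatenate([centers[:, None], negs], axis=1)
        U = model.output_weights[rows]
        scores = np.einsum("bkd,bd->bk", U, h)
        g = (_sigmoid(scores) - labels) * lr
        grad_h = np.einsum("bk,bkd->bd", g, U)
        vec -= (grad_h / denom).sum(axis=0)
    if not np.all(np.isfinite(vec)):
        raise FloatingPointError("non-finite inferred embedding")
    return vec


def infer_embedding_matrix(
    model: ParagraphVectorModel,
    descriptions: list[list[str]],
    epochs: int | None = None,
) -> np.ndarray:
    """Stacked :func:`infer_embedding` over documents."""
    return np.array([infer_embedding(model, doc, epochs=epochs) for doc in descriptions])
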