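"""Skip-gram word embeddings with negative sampling (SGNS).

Dense word vectors (default 300-dimensional) are trained unsupervised on
the merged token streams and used to initialize the embedding layer of
every classifier.  The implementation is a vectorized numpy SGNS: for each
(center, context) pair within a dynamically-shrunk window, the dot product
of the input vector of the center and the output vector of the context is
pushed up, while dot products with negative samples drawn from the
unigram^0.75 distribution are pushed down.

Reserved-token conventions: the PAD row is fixed at zero; the OOV row is a
small random vector with components bounded by 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .preprocessing import OOV, PAD, Vocabulary

OOV_INIT_BOUND = 0.01


@dataclass
class EmbeddingConfig:
    dimension: int = 300
    window: int = 5
    epochs: int = 5
    min_count: int = 1
    negative: int = 5
    learning_rate: float = 0.025
    batch_size: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.window < 1 or self.epochs < 0 or self.negative < 1:
            raise ValueError("window and negative must be >= 1, epochs >= 0")


@dataclass
class EmbeddingTable:
    """Vocabulary-aligned vector table: row i is the vector of token i."""

    vocab: Vocabulary
    matrix: np.ndarray  # (vocab.size, d)

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.vocab.size:
            raise ValueError("embedding row count must equal vocabulary size")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding table contains non-finite values")

    @property
    def dimension(self) -> int:
        return int(self.matrix.shape[1])

    def vector(self, token: str) -> np.ndarray:
        return self.matrix[self.vocab.lookup(token)]

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 0.0
        return float(va @ vb / (na * nb))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _training_pairs(
    streams: Iterable[Sequence[str]],
    vocab: Vocabulary,
    window: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(center, context) index pairs with per-center dynamic window size."""
    pairs: list[tuple[int, int]] = []
    pad_idx = vocab.index[PAD]
    oov_idx = vocab.index[OOV]
    for stream in streams:
        idx = [vocab.index[t] for t in stream if t in vocab]
        idx = [i for i in idx if i not in (pad_idx, oov_idx)]
        n = len(idx)
        for pos in range(n):
            b = int(rng.integers(1, window + 1))
            for off in range(-b, b + 1):
                j = pos + off
                if off != 0 and 0 <= j < n:
                    pairs.append((idx[pos], idx[j]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(pairs, dtype=np.int64)


def train_embeddings(
    token_streams: Sequence[Sequence[str]],
    config: EmbeddingConfig,
    vocab: Vocabulary,
) -> EmbeddingTable:
    """Train SGNS vectors for every vocabulary token.

    Deterministic given the seed (single-threaded numpy).  Tokens absent
    from the streams keep their random initialization; PAD and OOV rows are
    overwritten with their reserved conventions at the end.
    """
    rng = np.random.default_rng(config.seed)
    V, d = vocab.size, config.dimension
    W = rng.uniform(-0.5 / d, 0.5 / d, size=(V, d))
    C = np.zeros((V, d))

    pairs = _training_pairs(token_streams, vocab, config.window, rng)
    if len(pairs):
        # unigram^0.75 noise distribution over observed context tokens
        counts = np.bincount(pairs[:, 1], minlength=V).astype(float)
        noise = counts**0.75
        noise_sum = noise.sum()
        noise = noise / noise_sum if noise_sum > 0 else np.full(V, 1.0 / V)
        lr = config.learning_rate
        B = config.batch_size
        k = config.negative
        for _epoch in range(config.epochs):
            order = rng.permutation(len(pairs))
            for start in range(0, len(pairs), B):
                batch = pairs[order[start:start + B]]
                centers, contexts = batch[:, 0], batch[:, 1]
                negs = rng.choice(V, size=(len(batch), k), p=noise)
                w = W[centers]                              # (B, d)
                # positive pairs: push sigma(w.c_pos) toward 1
                c_pos = C[contexts]
                g_pos = (_sigmoid(np.sum(w * c_pos, axis=1)) - 1.0)[:, None]
                # negatives: push sigma(w.c_neg) toward 0
                c_neg = C[negs]                             # (B, k, d)
                g_neg = _sigmoid(np.einsum("bd,bkd->bk", w, c_neg))
                grad_w = g_pos * c_pos + np.einsum("bk,bkd->bd", g_neg, c_neg)
                np.add.at(C, contexts, -lr * g_pos * w)
                np.add.at(
                    C, negs.ravel(),
                    (-lr * g_neg[..., None] * w[:, None, :]).reshape(-1, d),
                )
                np.add.at(W, centers, -lr * grad_w)

    W[vocab.index[PAD]] = 0.0
    W[vocab.index[OOV]] = rng.uniform(-OOV_INIT_BOUND, OOV_INIT_BOUND, size=d)
    return EmbeddingTable(vocab=vocab, matrix=W)


def save_embedding_text(table: EmbeddingTable, path) -> None:
    """Standard whitespace-delimited text format: header 'size dim', then rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{table.vocab.size} {table.dimension}\n")
        for tok, row in zip(table.vocab.tokens(), table.matrix):
            fh.write(tok + " " + " ".join(f"{x:.6g}" for x in row) + "\n")


def load_embedding_text(path) -> EmbeddingTable:
    with open(path, encoding="utf-8") as fh:
        size, dim = map(int, fh.readline().split())
        index: dict[str, int] = {}
        matrix = np.zeros((size, dim))
        for i in range(size):
            parts = fh.readline().rstrip("\n").split(" ")
            index[parts[0]] = i
            matrix[i] = [float(x) for x in parts[1:]]
    return EmbeddingTable(vocab=Vocabulary(index), matrix=matrix)
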