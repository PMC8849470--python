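"""Skip-gram with negative sampling (SGNS) word embeddings.

A compact, deterministic word2vec-style trainer: for every (center,
context) pair within a dynamically shrunk window, the center vector is
pushed toward the context's output vector and away from k sampled
negatives (unigram^0.75 noise distribution), by logistic SGD with a
linearly decaying learning rate.  All randomness (window shrinkage,
negative draws, pair shuffling, initialization) comes from one seeded
generator; the SGD inner loop is a sequential numba kernel, so training
is reproducible at a fixed thread count (the kernel is single-threaded).

Defaults follow the hyperparameters used for the 45-million-sentence
German corpus model: 300 dimensions, window 5, minimum count 1,
50 iterations, skip-gram.  Negative-sampling count (5), learning rate
and subsampling (none) are not reported there and are declared here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .errors import ConfigError, MissingWordError

__all__ = ["EmbeddingHyperparams", "EmbeddingModel", "SkipGram", "train_embeddings"]


@dataclass(frozen=True)
class EmbeddingHyperparams:
    """Skip-gram training settings; defaults are the study's printed values."""

    dimensions: int = 300
    model_type: str = "skipgram"
    window_size: int = 5
    min_count: int = 1
    iterations: int = 50
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4

    def __post_init__(self) -> None:
        if self.model_type != "skipgram":
            raise ConfigError("only model_type='skipgram' is implemented")
        for name in ("dimensions", "window_size", "min_count", "iterations",
                     "negative"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if not 0 < self.min_alpha <= self.alpha:
            raise ConfigError("need 0 < min_alpha <= alpha")


@dataclass(frozen=True)
class EmbeddingModel:
    """Trained word vectors: an ordered vocabulary and a V x d matrix."""

    words: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != len(self.words):
            raise ConfigError("matrix rows must match the vocabulary")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "_index", {w: i for i, w in enumerate(self.words)})

    @property
    def dimensions(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.matrix[self._index[word]]
        except KeyError:
            raise MissingWordError(f"word {word!r} has no vector") from None

    def stack(self, words: Sequence[str]) -> np.ndarray:
        missing = [w for w in words if w not in self._index]
        if missing:
            raise MissingWordError(f"words without vectors: {missing}")
        return self.matrix[[self._index[w] for w in words]]


@njit(cache=True)
def _sgns_epoch(W, C, centers, contexts, negatives, lr_start, lr_end):  # pragma: no cover - jitted
    n_pairs = centers.shape[0]
    d = W.shape[1]
    k = negatives.shape[1]
    grad = np.empty(d, dtype=W.dtype)
    for p in range(n_pairs):
        lr = lr_start + (lr_end - lr_start) * (p / n_pairs)
        c = centers[p]
        pos = contexts[p]
        for f in range(d):
            grad[f] = 0.0
        for t in range(k + 1):
            if t == 0:
                o = pos
                label = 1.0
            else:
                o = negatives[p, t - 1]
                if o == pos:
                    continue
                label = 0.0
            dot = 0.0
            for f in range(d):
                dot += W[c, f] * C[o, f]
            if dot > 8.0:
                s = 1.0
            elif dot < -8.0:
                s = 0.0
            else:
                s = 1.0 / (1.0 + np.exp(-dot))
            g = lr * (label - s)
            for f in range(d):
                grad[f] += g * C[o, f]
                C[o, f] += g * W[c, f]
        for f in range(d):
            W[c, f] += grad[f]


class SkipGram:
    """Estimator-style SGNS trainer.

    Parameters are an :class:`EmbeddingHyperparams` (or keyword
    overrides of its defaults) plus a seed.  After :meth:`fit`,
    ``vocab_`` holds the kept vocabulary (count >= min_count, by
    descending frequency then first occurrence) and ``vectors_`` the
    input-vector matrix; :meth:`to_model` packages both.
    """

    def __init__(self, hyperparams: EmbeddingHyperparams | None = None,
                 seed: int = 0, **overrides):
        if hyperparams is None:
            hyperparams = EmbeddingHyperparams(**overrides)
        elif overrides:
            raise ConfigError("pass either hyperparams or keyword overrides")
        self.hyperparams = hyperparams
        self.seed = seed

    # -- vocabulary -------------------------------------------------------
    @staticmethod
    def _build_vocab(sentences, min_count):
        counts: dict[str, int] = {}
        order: dict[str, int] = {}
        for sent in sentences:
            for tok in sent:
                if tok not in counts:
                    order[tok] = len(order)
                    counts[tok] = 0
                counts[tok] += 1
        kept = [w for w, c in counts.items() if c >= min_count]
        kept.sort(key=lambda w: (-counts[w], order[w]))
        return kept, counts

    @staticmethod
    def _encode(sentences, index):
        flat, sent_id = [], []
        for s, sent in enumerate(sentences):
            for tok in sent:
                idx = index.get(tok)
                if idx is not None:
                    flat.append(idx)
                    sent_id.append(s)
        return (np.asarray(flat, dtype=np.int32),
                np.asarray(sent_id, dtype=np.int64))

    def _pairs(self, flat, sent_id, rng):
        """(center, context) pairs with per-center dynamic window shrink."""
        window = self.hyperparams.window_size
        b = rng.integers(1, window + 1, size=flat.size)
        centers, contexts = [], []
        for delta in range(1, window + 1):
            if delta >= flat.size:
                break
            same = sent_id[:-delta] == sent_id[delta:]
            fwd = same & (delta <= b[:-delta])
            centers.append(flat[:-delta][fwd])
            contexts.append(flat[delta:][fwd])
            bwd = same & (delta <= b[delta:])
            centers.append(flat[delta:][bwd])
            contexts.append(flat[:-delta][bwd])
        if not centers:
            return (np.zeros(0, np.int32),) * 2
        return np.concatenate(centers), np.concatenate(contexts)

    # -- training ---------------------------------------------------------
    def fit(self, sentences: Iterable[Sequence[str]]) -> "SkipGram":
        sentences = [list(s) for s in sentences]
        if not sentences:
            raise ConfigError("corpus is empty")
        hp = self.hyperparams
        vocab, counts = self._build_vocab(sentences, hp.min_count)
        if not vocab:
            raise ConfigError("vocabulary is empty after min_count filtering")
        index = {w: i for i, w in enumerate(vocab)}
        flat, sent_id = self._encode(sentences, index)

        rng = np.random.default_rng(self.seed)
        V, d = len(vocab), hp.dimensions
        W = ((rng.random((V, d)) - 0.5) / d).astype(np.float64)
        C = np.zeros((V, d), dtype=np.float64)

        freq = np.asarray([counts[w] for w in vocab], dtype=float) ** 0.75
        cum = np.cumsum(freq / freq.sum())

        for epoch in range(hp.iterations):
            centers, contexts = self._pairs(flat, sent_id, rng)
            if centers.size == 0:
                break
            perm = rng.permutation(centers.size)
            centers, contexts = centers[perm], contexts[perm]
            negatives = np.searchsorted(
                cum, rng.random((centers.size, hp.negative))
            ).astype(np.int32)
            span = hp.alpha - hp.min_alpha
            lr_start = hp.alpha - span * epoch / hp.iterations
            lr_end = hp.alpha - span * (epoch + 1) / hp.iterations
            _sgns_epoch(W, C, centers, contexts, negatives, lr_start, lr_end)

        self.vocab_ = tuple(vocab)
        self.vectors_ = W
        self.counts_ = {w: counts[w] for w in vocab}
        return self

    def to_model(self) -> EmbeddingModel:
        if not hasattr(self, "vectors_"):
            raise ConfigError("SkipGram is not fitted")
        return EmbeddingModel(self.vocab_, self.vectors_)


def train_embeddings(
    corpus: Iterable[Sequence[str]],
    hyperparams: EmbeddingHyperparams | None = None,
    seed: int = 0,
) -> EmbeddingModel:
    """Train skip-gram embeddings on a tokenized corpus (see SkipGram)."""
    return SkipGram(hyperparams or EmbeddingHyperparams(), seed=seed).fit(corpus).to_model()
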