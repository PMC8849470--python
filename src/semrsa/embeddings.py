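"""Corpus manipulation and distributional-semantics model RDMs.

Model families are built by training skip-gram embeddings on nested
prefix fragments of a corpus (the first n sentences, so smaller
fragments are always contained in larger ones) and on concreteness-
filtered variants: an abstract-only corpus keeps tokens with
concreteness z < 0, a concrete-only corpus keeps z > 0, in both cases
optionally retaining a set of target words so their relations to the
remaining words stay learnable.  A model RDM is the pairwise
correlation distance between word vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, MissingWordError
from .rdm import RDM, correlation_distance_rdm
from .sgns import EmbeddingHyperparams, EmbeddingModel, SkipGram, train_embeddings

__all__ = [
    "Corpus",
    "ConcretenessNorms",
    "EmbeddingHyperparams",
    "EmbeddingModel",
    "SkipGram",
    "train_embeddings",
    "fragment_corpus",
    "filter_corpus_by_concreteness",
    "model_rdm_from_embeddings",
    "read_corpus",
    "write_corpus",
    "read_embeddings_tsv",
    "write_embeddings_tsv",
]

logger = logging.getLogger(__name__)

#: a corpus is an ordered list of token lists (one sentence each)
Corpus = list

FILTER_MODES = ("abstract_only", "concrete_only")


@dataclass(frozen=True)
class ConcretenessNorms:
    """Per-word concreteness on a z-scaled axis (negative = abstract)."""

    z_by_word: dict

    def __post_init__(self) -> None:
        z = {str(w): float(v) for w, v in self.z_by_word.items()}
        if not all(np.isfinite(v) for v in z.values()):
            raise ConfigError("concreteness values must be finite")
        object.__setattr__(self, "z_by_word", z)

    def __contains__(self, word: str) -> bool:
        return word in self.z_by_word

    def __getitem__(self, word: str) -> float:
        try:
            return self.z_by_word[word]
        except KeyError:
            raise MissingWordError(f"no concreteness norm for {word!r}") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConcretenessNorms":
        df = pd.read_csv(path, sep="\t", dtype={"word": str})
        if not {"word", "z"} <= set(df.columns):
            raise ConfigError("norms TSV needs columns 'word' and 'z'")
        return cls(dict(zip(df["word"], df["z"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"word": list(self.z_by_word), "z": list(self.z_by_word.values())}
        ).to_csv(path, sep="\t", index=False)


def fragment_corpus(corpus: Corpus, n: int) -> Corpus:
    """The first min(n, len(corpus)) sentences, in original order.

    Fragments are nested by construction: fragment(c, a) is an exact
    prefix of fragment(c, b) whenever a <= b.
    """
    if n < 1:
        raise ConfigError("fragment size must be >= 1")
    return [list(s) for s in corpus[:n]]


def filter_corpus_by_concreteness(
    corpus: Corpus,
    norms: ConcretenessNorms,
    mode: str,
    keep_words: Iterable[str] = (),
) -> Corpus:
    """Token-level concreteness filtering of a corpus.

    A token survives iff its norm is z < 0 (``abstract_only``) or z > 0
    (``concrete_only``) — strict inequalities, so z = 0 words are
    excluded from both — or it belongs to ``keep_words`` (e.g. the
    target stimuli retained in the concrete-only corpus).  Tokens
    without a norm entry are dropped and counted in the log.  Sentence
    order is preserved and emptied sentences are removed.
    """
    if mode not in FILTER_MODES:
        raise ConfigError(f"mode must be one of {FILTER_MODES}")
    keep = set(keep_words)
    sign = -1.0 if mode == "abstract_only" else 1.0
    out = []
    n_dropped = n_missing = 0
    for sent in corpus:
        kept = []
        for tok in sent:
            if tok in keep:
                kept.append(tok)
            elif tok not in norms:
                n_missing += 1
            elif sign * norms[tok] > 0:
                kept.append(tok)
            else:
                n_dropped += 1
        if kept:
            out.append(kept)
    logger.info(
        "concreteness filter (%s): dropped %d classified and %d un-normed tokens; "
        "%d of %d sentences survive", mode, n_dropped, n_missing, len(out), len(corpus)
    )
    return out


def model_rdm_from_embeddings(model: EmbeddingModel, words: Sequence[str]) -> RDM:
    """Correlation-distance RDM over the vectors of an ordered word list."""
    words = [str(w) for w in words]
    return correlation_distance_rdm(model.stack(words), words)


# ---------------------------------------------------------------------------
# plain-text interchange formats


def read_corpus(path: str | Path) -> Corpus:
    """One sentence per line, whitespace-separated tokens; blank lines skipped."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            toks = line.split()
            if toks:
                out.append(toks)
    return out


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in corpus:
            fh.write(" ".join(sent) + "\n")


def write_embeddings_tsv(model: EmbeddingModel, path: str | Path) -> None:
    cols = [f"v{i}" for i in range(model.dimensions)]
    df = pd.DataFrame(model.matrix, columns=cols)
    df.insert(0, "word", list(model.words))
    df.to_csv(path, sep="\t", index=False)


def read_embeddings_tsv(path: str | Path) -> EmbeddingModel:
    df = pd.read_csv(path, sep="\t", dtype={"word": str})
    words = tuple(df["word"])
    return EmbeddingModel(words, df.drop(columns="word").to_numpy(dtype=float))
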