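"""Word embeddings: skip-gram with negative sampling, trained from scratch.

The trainer is a deterministic, single-threaded re-implementation of the
classic word2vec skip-gram objective with a unigram^0.75 negative-sampling
distribution.  Similarity queries use cosine over the input vectors, which
is the convention the rest of the pipeline (lexicon expansion, similarity
reports) relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import sgns_train
from .corpus_io import TokenDoc, Vocabulary

__all__ = [
    "TrainConfig",
    "EmbeddingModel",
    "OOVError",
    "train",
    "similarity",
    "most_similar",
    "similarity_report",
]


class OOVError(KeyError):
    """A queried term is not in the embedding vocabulary."""


@dataclass(frozen=True)
class TrainConfig:
    dim: int = 100
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    min_count: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class EmbeddingModel:
    vocab: Vocabulary
    w_in: np.ndarray  # V x dim input (center-word) vectors
    w_out: np.ndarray  # V x dim output (context) vectors
    config: Optional[TrainConfig] = None

    def vector(self, term: str) -> np.ndarray:
        try:
            return self.w_in[self.vocab[term]]
        except KeyError:
            raise OOVError(term) from None

    def save(self, vocab_path, matrix_path) -> None:
        with open(vocab_path, "w", encoding="utf-8") as fh:
            for t in self.vocab.id2term:
                fh.write(t + "\n")
        np.savez(matrix_path, w_in=self.w_in, w_out=self.w_out)

    @classmethod
    def load(cls, vocab_path, matrix_path) -> "EmbeddingModel":
        with open(vocab_path, encoding="utf-8") as fh:
            terms = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        arrs = np.load(matrix_path if str(matrix_path).endswith(".npz") else f"{matrix_path}.npz")
        return cls(vocab=Vocabulary(terms), w_in=arrs["w_in"], w_out=arrs["w_out"])


def _build_vocab(corpus: Sequence[TokenDoc], min_count: int) -> Vocabulary:
    freq: dict[str, int] = {}
    for doc in corpus:
        for t in doc.tokens:
            freq[t] = freq.get(t, 0) + 1
    kept = [(t, c) for t, c in freq.items() if c >= min_count]
    if not kept:
        raise ValueError(f"vocabulary is empty after min_count={min_count} filtering")
    # frequency-descending, term-ascending: stable and conventional
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    vocab = Vocabulary([t for t, _ in kept])
    vocab.counts = np.array([c for _, c in kept], dtype=np.int64)  # type: ignore[attr-defined]
    return vocab


def _negative_table(counts: np.ndarray, size: int = 200_000) -> np.ndarray:
    weights = counts.astype(np.float64) ** 0.75
    cum = np.cumsum(weights / weights.sum())
    positions = (np.arange(size) + 0.5) / size
    return np.searchsorted(cum, positions).astype(np.int32)


def train(corpus: Sequence[TokenDoc], config: TrainConfig = TrainConfig()) -> EmbeddingModel:
    """Train skip-gram-negative-sampling vectors on token documents.

    Deterministic for a given seed: initialization comes from a seeded
    NumPy generator and the update loop runs single-threaded with its own
    internal generator.
    """
    vocab = _build_vocab(corpus, config.min_count)
    v = len(vocab)
    encoded: list[np.ndarray] = []
    for doc in corpus:
        ids = [vocab.term2id[t] for t in doc.tokens if t in vocab.term2id]
        if ids:
            encoded.append(np.array(ids, dtype=np.int32))
    if not encoded:
        raise ValueError("no documents survive vocabulary filtering")
    words = np.concatenate(encoded)
    offsets = np.zeros(len(encoded) + 1, dtype=np.int64)
    np.cumsum([len(e) for e in encoded], out=offsets[1:])

    rng = np.random.default_rng(config.seed)
    w_in = rng.uniform(-0.5, 0.5, size=(v, config.dim)) / config.dim
    w_out = np.zeros((v, config.dim), dtype=np.float64)
    neg_table = _negative_table(vocab.counts)  # type: ignore[attr-defined]
    sgns_train(
        words,
        offsets,
        config.window,
        config.negatives,
        config.learning_rate,
        config.epochs,
        w_in,
        w_out,
        neg_table,
        config.seed,
    )
    return EmbeddingModel(vocab=vocab, w_in=w_in, w_out=w_out, config=config)


def similarity(model: EmbeddingModel, w1: str, w2: str) -> float:
    """Cosine similarity between the input vectors of two in-vocabulary terms."""
    a = model.vector(w1)
    b = model.vector(w2)
    denom = float(np.linalg.norm(a) * np.linalg.norm(b))
    if denom == 0.0:
        return 0.0
    return float(np.dot(a, b) / denom)


def most_similar(model: EmbeddingModel, w: str, k: int) -> list[tuple[str, float]]:
    """Top-k nearest vocabulary terms by cosine, excluding the query term.

    Ties are broken by lexicographic term order; at most V-1 entries are
    returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    qi = model.vocab.term2id.get(w)
    if qi is None:
        raise OOVError(w)
    q = model.w_in[qi]
    norms = np.linalg.norm(model.w_in, axis=1)
    qn = norms[qi]
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = (model.w_in @ q) / (norms * qn)
    sims = np.nan_to_num(sims, nan=0.0)
    order = sorted(
        (i for i in range(len(model.vocab)) if i != qi),
        key=lambda i: (-sims[i], model.vocab.id2term[i]),
    )
    return [(model.vocab.id2term[i], float(sims[i])) for i in order[:k]]


def similarity_report(model: EmbeddingModel, probes: Sequence[tuple]) -> pd.DataFrame:
    """Tabulate probe-pair cosine similarities as percentages (two decimals).

    Out-of-vocabulary probes are flagged (``in_vocab=False``, NaN score)
    rather than fatal, so a report over a mixed probe list always completes.
    """
    rows = []
    for w1, w2 in probes:
        if w1 in model.vocab and w2 in model.vocab:
            pct = round(100.0 * similarity(model, w1, w2), 2)
            rows.append({"term1": w1, "term2": w2, "similarity_pct": pct, "in_vocab": True})
        else:
            rows.append({"term1": w1, "term2": w2, "similarity_pct": float("nan"), "in_vocab": False})
    return pd.DataFrame(rows, columns=["term1", "term2", "similarity_pct", "in_vocab"])
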