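"""Latent Dirichlet Allocation via collapsed Gibbs sampling.

The sampler uses the standard collapsed conditional
``p(z_i = k) ∝ (n_dk + α)(n_kw + β) / (n_k + Vβ)`` and reports φ (topic-word)
and θ (document-topic) as smoothed estimates averaged over post-burn-in
samples.  Model selection follows the usual recipe: fit a range of K and
pick the one with the lowest validation perplexity, reporting NPMI topic
coherence alongside.  Perplexity on held-out documents uses fold-in
sampling: φ stays fixed while θ' is re-estimated per held-out document.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._kernels import lda_foldin, lda_gibbs
from .corpus_io import BOWCorpus

__all__ = [
    "LDAConfig",
    "LDAModel",
    "TopicSummary",
    "fit",
    "perplexity",
    "npmi_coherence",
    "summarize",
    "select_num_topics",
    "split_corpus",
]


@dataclass(frozen=True)
class LDAConfig:
    K: int
    alpha: Optional[float] = None  # None -> 50 / K
    beta: float = 0.01
    iterations: int = 500
    burn_in: int = 300
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")

    @property
    def alpha_value(self) -> float:
        return 50.0 / self.K if self.alpha is None else self.alpha


@dataclass
class LDAModel:
    phi: np.ndarray  # K x V topic-word distribution
    theta: np.ndarray  # D x K document-topic distribution
    assignments: np.ndarray  # final token-topic assignments
    config: LDAConfig
    vocab_terms: list[str]
    nkw: Optional[np.ndarray] = None  # final topic-word counts (conservation checks)
    ndk: Optional[np.ndarray] = None


def _expand_tokens(matrix: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    coo = matrix.tocoo()
    reps = coo.data.astype(np.int64)
    words = np.repeat(coo.col.astype(np.int32), reps)
    docs = np.repeat(coo.row.astype(np.int32), reps)
    order = np.lexsort((words, docs))
    return words[order], docs[order]


def fit(corpus: BOWCorpus, config: LDAConfig) -> LDAModel:
    """Run the collapsed Gibbs sampler; deterministic for a given seed."""
    if corpus.n_docs == 0 or corpus.n_tokens == 0:
        raise ValueError("cannot fit LDA on an empty corpus")
    words, docs = _expand_tokens(corpus.matrix)
    z, phi, theta, nkw, ndk = lda_gibbs(
        words,
        docs,
        corpus.n_docs,
        len(corpus.vocab),
        config.K,
        config.alpha_value,
        config.beta,
        config.iterations,
        config.burn_in,
        config.thin,
        config.seed,
    )
    return LDAModel(
        phi=phi,
        theta=theta,
        assignments=z,
        config=config,
        vocab_terms=list(corpus.vocab.id2term),
        nkw=nkw,
        ndk=ndk,
    )


def perplexity(model: LDAModel, heldout: BOWCorpus, foldin_iterations: int = 60,
               foldin_burn_in: int = 20, seed: Optional[int] = None,
               completion: bool = True) -> float:
    """exp(-Σ log p(w|d) / N) on held-out documents, θ' by fold-in sampling.

    With ``completion=True`` (the default) each held-out document is split
    in half: θ' is folded in on the estimation half and the likelihood is
    scored on the other half.  This document-completion scheme keeps θ'
    honest — estimating it on the scored tokens themselves rewards extra
    topics and biases model selection upward in K.  Held-out terms missing
    from the model vocabulary are dropped (and do not contribute to N).
    """
    term2id = {t: i for i, t in enumerate(model.vocab_terms)}
    # remap held-out columns into the model vocabulary
    col_map = np.array(
        [term2id.get(t, -1) for t in heldout.vocab.id2term], dtype=np.int64
    )
    est_words, est_docs, ev_words, ev_docs = [], [], [], []
    indptr = heldout.matrix.indptr
    indices = heldout.matrix.indices
    data = heldout.matrix.data
    for d in range(heldout.n_docs):
        toks = []
        for p in range(indptr[d], indptr[d + 1]):
            w = col_map[indices[p]]
            if w >= 0:
                toks.extend([int(w)] * int(data[p]))
        if not completion:
            est_words.extend(toks)
            est_docs.extend([d] * len(toks))
            ev_words.extend(toks)
            ev_docs.extend([d] * len(toks))
            continue
        # deterministic alternating split of each document's token multiset
        est, ev = toks[0::2], toks[1::2]
        est_words.extend(est)
        est_docs.extend([d] * len(est))
        ev_words.extend(ev)
        ev_docs.extend([d] * len(ev))
    if not ev_words:
        raise ValueError("no held-out tokens overlap the model vocabulary")
    theta_p = lda_foldin(
        np.array(est_words, dtype=np.int32),
        np.array(est_docs, dtype=np.int32),
        heldout.n_docs,
        model.phi,
        model.config.alpha_value,
        foldin_iterations,
        foldin_burn_in,
        model.config.seed if seed is None else seed,
    )
    ev_w = np.array(ev_words, dtype=np.int64)
    ev_d = np.array(ev_docs, dtype=np.int64)
    probs = np.einsum("nk,kn->n", theta_p[ev_d], model.phi[:, ev_w])
    return float(np.exp(-np.mean(np.log(probs))))


def npmi_coherence(
    corpus: BOWCorpus,
    top_words: Sequence[str],
    epsilon: float = 1e-12,
) -> float:
    """Mean pairwise NPMI of a topic's top words, in [-1, 1].

    Co-occurrence is counted at document level: p(w) = df(w)/D and
    p(wi, wj) = df(wi AND wj)/D, with ε added to the joint so never-
    co-occurring pairs stay finite.  NPMI(wi,wj) =
    log(p_ij / (p_i p_j)) / (-log p_ij).  Pairs with a word absent from the
    corpus are skipped.
    """
    if len(top_words) < 2:
        raise ValueError("need at least two top words")
    d_total = corpus.n_docs
    presence = {}
    for w in dict.fromkeys(top_words):
        j = corpus.vocab.term2id.get(w)
        if j is None:
            continue
        col = corpus.matrix[:, j]
        present = np.zeros(d_total, dtype=bool)
        present[col.tocoo().row] = True
        if present.any():
            presence[w] = present
    vals = []
    for wi, wj in combinations([w for w in dict.fromkeys(top_words) if w in presence], 2):
        p_i = presence[wi].sum() / d_total
        p_j = presence[wj].sum() / d_total
        p_ij = (presence[wi] & presence[wj]).sum() / d_total + epsilon
        if p_ij >= 1.0:
            vals.append(0.0)  # ubiquitous pair: PMI is exactly 0
            continue
        vals.append(math.log(p_ij / (p_i * p_j)) / (-math.log(p_ij)))
    if not vals:
        raise ValueError("no top-word pair occurs in the corpus")
    return float(np.mean(vals))


@dataclass
class TopicSummary:
    table: pd.DataFrame  # topic, top_words, coherence, word_share_pct (coherence-sorted)

    @property
    def word_shares(self) -> np.ndarray:
        return self.table["word_share_pct"].to_numpy()


def top_words(model: LDAModel, topic: int, n: int) -> list[str]:
    """Top-n words of one topic by φ, ties broken lexicographically."""
    row = model.phi[topic]
    order = sorted(range(len(row)), key=lambda j: (-row[j], model.vocab_terms[j]))
    return [model.vocab_terms[j] for j in order[:n]]


def summarize(model: LDAModel, corpus: BOWCorpus, top_n: int = 12) -> TopicSummary:
    """Per-topic top words, NPMI coherence, and vocabulary share.

    Word share assigns every vocabulary word to its argmax topic (ties to
    the lowest topic index), so shares partition 100% across topics.
    Topics are reported in decreasing coherence.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    argmax = model.phi.argmax(axis=0)  # np.argmax ties -> lowest index
    v = model.phi.shape[1]
    rows = []
    for k in range(model.config.K):
        words = top_words(model, k, top_n)
        rows.append(
            {
                "topic": k,
                "top_words": words,
                "coherence": npmi_coherence(corpus, words),
                "word_share_pct": round(100.0 * float((argmax == k).sum()) / v, 4),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "coherence", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return TopicSummary(table=table)


def split_corpus(corpus: BOWCorpus, val_fraction: float = 0.1, seed: int = 0):
    """Seed-controlled by-document train/validation split."""
    rng = np.random.default_rng(seed)
    d = corpus.n_docs
    n_val = max(1, int(round(d * val_fraction)))
    if n_val >= d:
        raise ValueError("validation split would consume the whole corpus")
    perm = rng.permutation(d)
    val_idx = np.sort(perm[:n_val])
    train_idx = np.sort(perm[n_val:])

    def _subset(idx):
        return BOWCorpus(
            vocab=corpus.vocab,
            matrix=corpus.matrix[idx],
            doc_ids=[corpus.doc_ids[i] for i in idx],
        )

    return _subset(train_idx), _subset(val_idx)


def select_num_topics(
    corpus: BOWCorpus,
    ks: Sequence[int],
    base_config: Optional[dict] = None,
    val_fraction: float = 0.1,
    seed: int = 0,
    top_n: int = 12,
) -> pd.DataFrame:
    """Fit each candidate K on a train split and score validation perplexity
    and mean NPMI coherence; the conventional choice is the K with the
    lowest validation perplexity (and the highest coherence as tiebreaker).
    """
    base = dict(base_config or {})
    base.pop("K", None)
    # Candidate models must share hyperparameters for a fair comparison:
    # the per-K heuristic alpha = 50/K hands larger K more document-topic
    # smoothing and systematically drags the perplexity minimum upward in K.
    base.setdefault("alpha", 0.1)
    train, val = split_corpus(corpus, val_fraction=val_fraction, seed=seed)
    rows = []
    for k in ks:
        cfg = LDAConfig(K=k, seed=seed, **base)
        model = fit(train, cfg)
        pp = perplexity(model, val)
        coh = float(
            np.mean([npmi_coherence(train, top_words(model, t, top_n)) for t in range(k)])
        )
        rows.append({"K": k, "val_perplexity": pp, "mean_coherence": coh})
    df = pd.DataFrame(rows)
    df["selected"] = False
    best = df.sort_values(["val_perplexity", "mean_coherence"], ascending=[True, False]).index[0]
    df.loc[best, "selected"] = True
    return df
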