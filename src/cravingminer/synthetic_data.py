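"""Synthetic forum-corpus generation with known ground truth.

The generator emulates the statistical structure of a sobriety-forum
craving corpus rather than its natural language: filler text is drawn from
an LDA generative model over an artificial vocabulary (``w000`` ...), so
that planted craving terms, context terms, topic structure, posting times
and sobriety badges can all be recovered and checked exactly.

Defaults encode the study conditions the pipeline is built for: ~70% of
authors write a single post, posts average 105 words, ~16% of posts are
craving posts, diurnal posting intensity peaks between 13:00 and 23:00
local time, and sobriety-badge day counts decay geometrically with excess
mass on the milestone days 30, 100 and 365.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .context_analysis import load_default_registry
from .corpus_io import BOWCorpus, LabeledPost, Post, TokenDoc, Vocabulary
from .craving_filter import SEED_TERMS

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_topic_corpus",
    "generate_labeled_testset",
    "generate_synonym_corpus",
    "unique_context_terms",
]

_EPOCH_START = 1491004800  # 2017-04-01 00:00 UTC
_EPOCH_END = 1648771200  # 2022-04-01 00:00 UTC
_UTC_OFFSETS = (-480, -420, -360, -300, -240, -180, 0, 60, 120)


def _default_context_rates() -> dict:
    # per-author injection rates, loosely shaped like the reported
    # craving-set author percentages so synthetic reports look realistic
    return {
        "work": 0.50, "anxious/worried": 0.45, "home": 0.39, "partner": 0.36,
        "family": 0.36, "happy": 0.36, "friend(s)": 0.34, "sad": 0.30,
        "frustrated/angry": 0.26, "workout": 0.19, "proud": 0.19, "alone": 0.18,
        "tired": 0.18, "stressed": 0.17, "restaurant/bar": 0.17, "supermarket": 0.16,
        "party": 0.13, "bored": 0.12, "university/school": 0.10,
        "colleague(s)": 0.04, "airport": 0.02,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_authors: int = 500
    single_post_author_fraction: float = 0.70
    mean_post_words: float = 105.0
    craving_rate: float = 0.16
    context_rates: dict = field(default_factory=_default_context_rates)
    n_topics_true: int = 5
    vocab_size: int = 300
    topic_word_concentration: float = 0.1
    doc_topic_concentration: float = 0.3
    diurnal_peak_window: tuple = (13, 23)
    diurnal_peak_ratio: float = 3.0
    flair_prob: float = 0.8
    flair_decay_rate: float = 0.02  # geometric success probability per day
    max_flair_days: int = 2000
    milestone_days: frozenset = frozenset({30, 100, 365})
    milestone_boost: float = 8.0
    # probabilities of injecting a craving seed as stem / +s / +ing / compound
    inflection_probs: tuple = (0.55, 0.15, 0.15, 0.15)

    def __post_init__(self) -> None:
        for p in (self.single_post_author_fraction, self.craving_rate, self.flair_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(not 0.0 <= r <= 1.0 for r in self.context_rates.values()):
            raise ValueError("context rates must lie in [0, 1]")
        lo, hi = self.diurnal_peak_window
        if not (0 <= lo <= 23 and 0 <= hi <= 23):
            raise ValueError("diurnal window hours must lie in 0..23")
        if self.diurnal_peak_ratio < 1.0:
            raise ValueError("diurnal_peak_ratio must be >= 1")
        if self.milestone_boost < 1.0:
            raise ValueError("milestone_boost must be >= 1")
        if self.n_authors < 1:
            raise ValueError("need at least one author")
        if abs(sum(self.inflection_probs) - 1.0) > 1e-9:
            raise ValueError("inflection_probs must sum to 1")


@dataclass
class GroundTruth:
    craving: dict[str, bool]
    contexts: dict[str, frozenset]
    topic_mixture: dict[str, np.ndarray]
    flair_days: dict[str, Optional[int]]
    author_contexts: dict[str, frozenset]
    phi_true: np.ndarray


def unique_context_terms(registry=None) -> dict[str, tuple]:
    """Terms belonging to exactly one category (safe to inject without
    cross-labeling; e.g. 'wife' is in both family and partner and is
    therefore never injected)."""
    registry = registry if registry is not None else load_default_registry()
    count: dict[str, int] = {}
    for q in registry:
        for t in q.terms:
            count[t] = count.get(t, 0) + 1
    return {q.category: tuple(t for t in q.terms if count[t] == 1) for q in registry}


def _inflect(stem: str, kind: int) -> str:
    if kind == 0:
        return stem
    if kind == 1:
        return stem + "s"
    if kind == 2:
        if stem.endswith("ing"):
            return stem
        return (stem[:-1] if stem.endswith("e") else stem) + "ing"
    return "alcohol-" + stem


def _flair_weights(config: GeneratorConfig) -> np.ndarray:
    d = np.arange(1, config.max_flair_days + 1, dtype=np.float64)
    p = config.flair_decay_rate
    w = p * (1.0 - p) ** (d - 1.0)
    for m in config.milestone_days:
        if 1 <= m <= config.max_flair_days:
            w[m - 1] *= config.milestone_boost
    return w / w.sum()


def _hour_weights(config: GeneratorConfig) -> np.ndarray:
    lo, hi = config.diurnal_peak_window
    w = np.ones(24, dtype=np.float64)
    hours = np.arange(24)
    if lo <= hi:
        peak = (hours >= lo) & (hours <= hi)
    else:  # window wrapping midnight
        peak = (hours >= lo) | (hours <= hi)
    w[peak] = config.diurnal_peak_ratio
    return w / w.sum()


def generate_corpus(config: GeneratorConfig = GeneratorConfig()):
    """Generate (posts, ground truth), fully reproducible from config.seed.

    Author-level randomness comes from a stream keyed by (seed, author
    index), so the first N authors are identical across corpora that differ
    only in n_authors.
    """
    corpus_rng = np.random.default_rng([config.seed, 982451653])
    k, v = config.n_topics_true, config.vocab_size
    phi = corpus_rng.dirichlet(np.full(v, config.topic_word_concentration), size=k)
    filler_vocab = np.array([f"w{i:03d}" for i in range(v)])
    uniq_terms = unique_context_terms()
    active_contexts = [
        (cat, rate, uniq_terms[cat])
        for cat, rate in sorted(config.context_rates.items())
        if rate > 0
    ]
    for cat, _rate, terms in active_contexts:
        if not terms:
            raise ValueError(f"category {cat!r} has no uniquely-owned term to inject")
    hour_w = _hour_weights(config)
    flair_w = _flair_weights(config)
    n_days = (_EPOCH_END - _EPOCH_START) // 86400

    posts: list[Post] = []
    truth = GroundTruth(
        craving={}, contexts={}, topic_mixture={}, flair_days={},
        author_contexts={}, phi_true=phi,
    )
    for a in range(config.n_authors):
        rng = np.random.default_rng([config.seed, 77003, a])
        author = f"author{a:06d}"
        if rng.random() < config.single_post_author_fraction:
            n_posts = 1
        else:
            n_posts = 1 + rng.geometric(0.5)
        offset = int(rng.choice(_UTC_OFFSETS))
        flair = int(rng.choice(len(flair_w), p=flair_w)) + 1 if rng.random() < config.flair_prob else None
        truth.flair_days[author] = flair

        # per-author context injection: each active category independently
        injected: dict[int, list[tuple[str, str]]] = {i: [] for i in range(n_posts)}
        author_cats = set()
        for cat, rate, terms in active_contexts:
            if rng.random() < rate:
                post_idx = int(rng.integers(n_posts))
                term = str(terms[int(rng.integers(len(terms)))])
                injected[post_idx].append((cat, term))
                author_cats.add(cat)
        truth.author_contexts[author] = frozenset(author_cats)

        for i in range(n_posts):
            post_id = f"p{a:06d}_{i:02d}"
            theta = rng.dirichlet(np.full(k, config.doc_topic_concentration))
            length = max(20, int(rng.poisson(config.mean_post_words)))
            z_counts = rng.multinomial(length, theta)
            blocks = [
                rng.choice(v, size=int(c), p=phi[kk])
                for kk, c in enumerate(z_counts)
                if c
            ]
            ids = np.concatenate(blocks)
            rng.shuffle(ids)
            tokens = [str(filler_vocab[j]) for j in ids]
            is_craving = bool(rng.random() < config.craving_rate)
            if is_craving:
                stem = str(SEED_TERMS[int(rng.integers(len(SEED_TERMS)))])
                kind = int(rng.choice(4, p=config.inflection_probs))
                tokens.insert(int(rng.integers(len(tokens) + 1)), _inflect(stem, kind))
            cats = []
            for cat, term in injected[i]:
                tokens.insert(int(rng.integers(len(tokens) + 1)), term)
                cats.append(cat)
            title = " ".join(tokens[:4])
            body = " ".join(tokens[4:])
            day = int(rng.integers(n_days))
            hour = int(rng.choice(24, p=hour_w))
            local_ts = (
                _EPOCH_START + day * 86400 + hour * 3600
                + int(rng.integers(60)) * 60 + int(rng.integers(60))
            )
            posts.append(
                Post(
                    id=post_id,
                    author=author,
                    title=title,
                    body=body,
                    created_utc=local_ts - offset * 60,
                    utc_offset_minutes=offset,
                    flair_days=flair,
                )
            )
            truth.craving[post_id] = is_craving
            truth.contexts[post_id] = frozenset(cats)
            truth.topic_mixture[post_id] = theta
    return posts, truth


def generate_topic_corpus(
    K: int, V: int, D: int, doc_len: int, alpha: float, beta: float, seed: int = 0
):
    """Sample a corpus from the exact LDA generative process.

    Returns (BOWCorpus, phi_true K x V, theta_true D x K).  phi rows are
    Dirichlet(beta) draws, each document's theta a Dirichlet(alpha) draw;
    tokens are drawn topic-first.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if V <= K:
        raise ValueError("V must exceed K")
    rng = np.random.default_rng([seed, 31337])
    phi = rng.dirichlet(np.full(V, beta), size=K)
    terms = [f"t{i:04d}" for i in range(V)]
    if D == 0:
        empty = sp.csr_matrix((0, V), dtype=np.int64)
        return (
            BOWCorpus(vocab=Vocabulary(terms), matrix=empty, doc_ids=[]),
            phi,
            np.zeros((0, K)),
        )
    theta = rng.dirichlet(np.full(K, alpha), size=D)
    rows = np.empty((D, V), dtype=np.int64)
    for d in range(D):
        z_counts = rng.multinomial(doc_len, theta[d])
        counts = np.zeros(V, dtype=np.int64)
        for kk in range(K):
            if z_counts[kk]:
                counts += rng.multinomial(z_counts[kk], phi[kk])
        rows[d] = counts
    mat = sp.csr_matrix(rows)
    vocab = Vocabulary(terms, doc_freq=(rows > 0).sum(axis=0))
    return BOWCorpus(vocab=vocab, matrix=mat, doc_ids=[f"doc{d:05d}" for d in range(D)]), phi, theta


def generate_labeled_testset(
    posts: Sequence[Post], truth: GroundTruth, n: int, seed: int = 0
) -> list[LabeledPost]:
    """Uniform sample of n posts without replacement, labels from ground truth."""
    if n > len(posts):
        raise ValueError(f"cannot sample {n} posts from a corpus of {len(posts)}")
    rng = np.random.default_rng([seed, 555557])
    idx = rng.choice(len(posts), size=n, replace=False)
    out = []
    for i in idx:
        p = posts[int(i)]
        out.append(
            LabeledPost(
                post_id=p.id,
                craving_label=truth.craving[p.id],
                context_labels=truth.contexts[p.id],
            )
        )
    return out


def generate_synonym_corpus(
    n_pairs: int = 6,
    n_background: int = 60,
    sentences_per_pair: int = 250,
    n_filler: int = 800,
    seed: int = 0,
):
    """Corpus with planted interchangeable-context token pairs.

    Each pair (synaI, synbI) owns four dedicated context tokens; in every
    pair sentence the two members are substituted for each other uniformly
    at random within identical context distributions, which is exactly the
    distributional-hypothesis setting word embeddings are meant to recover.
    Returns (token docs, list of (a, b) pairs).
    """
    rng = np.random.default_rng([seed, 424243])
    background = [f"bg{i:03d}" for i in range(n_background)]
    docs: list[TokenDoc] = []
    pairs = []
    did = 0
    for i in range(n_pairs):
        a, b = f"syna{i}", f"synb{i}"
        pairs.append((a, b))
        ctx = [f"ctx{i}_{j}" for j in range(4)]
        for _ in range(sentences_per_pair):
            member = a if rng.random() < 0.5 else b
            order = list(rng.permutation(ctx))
            toks = order[:2] + [member] + order[2:]
            toks += [background[int(j)] for j in rng.integers(n_background, size=3)]
            docs.append(TokenDoc(post_id=f"s{did:06d}", tokens=toks))
            did += 1
    for _ in range(n_filler):
        toks = [background[int(j)] for j in rng.integers(n_background, size=int(rng.integers(8, 16)))]
        docs.append(TokenDoc(post_id=f"s{did:06d}", tokens=toks))
        did += 1
    order = rng.permutation(len(docs))
    return [docs[int(i)] for i in order], pairs
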