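"""Craving-post detection: lexicon expansion, word-form patterns, evaluation.

A craving lexicon starts from six literature-derived seed synonyms
('craving', 'trigger', 'relapse', 'urge', 'desire', 'temptation'), is
optionally expanded with each seed's nearest embedding neighbors, and is
compiled into a case-insensitive word-form pattern that also matches
affixed forms ("cravings", "triggered", "relapsing") and hyphenated
compounds ("alcohol-craving").  Affix matching uses a curated inventory of
common English prefixes and suffixes rather than arbitrary in-token
substrings, so that e.g. a stem "bar" can never match "barely": every match
is a whole token composed of ``prefix + stem + suffix``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

from .corpus_io import CleanCorpus, LabeledPost, Post
from .embeddings import EmbeddingModel, most_similar

__all__ = [
    "SEED_TERMS",
    "Lexicon",
    "WordFormPattern",
    "ConfusionMatrix",
    "EvalResult",
    "FilterResult",
    "expand_lexicon",
    "compile_pattern",
    "filter_corpus",
    "evaluate",
]

SEED_TERMS = ("craving", "trigger", "relapse", "urge", "desire", "temptation")

PREFIXES = ("un", "re", "de", "non", "dis", "mis", "pre", "anti", "over", "under")
SUFFIXES = (
    "s", "es", "ed", "d", "ing", "ings", "er", "ers", "or", "ors",
    "ion", "ions", "ive", "ives", "y", "al", "ally", "able", "ful",
    "less", "ness", "ment", "ments",
)
_VOWEL_INITIAL = tuple(s for s in SUFFIXES if s[0] in "aeiou")


@dataclass(frozen=True)
class Lexicon:
    name: str
    seed_terms: tuple
    expanded_terms: tuple = ()
    curated: bool = False
    oov_seeds: tuple = ()

    @property
    def terms(self) -> tuple:
        seen = dict.fromkeys(self.seed_terms)
        seen.update(dict.fromkeys(self.expanded_terms))
        return tuple(seen)


def word_forms(stem: str) -> frozenset:
    """Enumerate the affixed word forms a stem is allowed to match.

    prefix + core + suffix, where core is the stem itself or, for
    vowel-initial suffixes, the stem with a trailing 'e' elided
    ("urge" -> "urging", "relapse" -> "relapsing").
    """
    stem = stem.lower()
    cores = [(stem, ("",) + SUFFIXES)]
    if stem.endswith("e"):
        cores.append((stem[:-1], _VOWEL_INITIAL))
    forms = set()
    for core, suffixes in cores:
        for suf in suffixes:
            for pre in ("",) + PREFIXES:
                forms.add(pre + core + suf)
    return frozenset(forms)


@dataclass
class WordFormPattern:
    lexicon_name: str
    forms: frozenset
    regex: re.Pattern = field(repr=False, default=None)  # type: ignore[assignment]

    def matches(self, text: str) -> bool:
        return self.regex.search(text) is not None

    def findall(self, text: str) -> list[str]:
        return [m.lower() for m in self.regex.findall(text)]


def compile_pattern(lexicon: Lexicon) -> WordFormPattern:
    """Compile a lexicon into a boundary-aware, case-insensitive pattern.

    Hyphenated compounds match naturally because a hyphen is a word
    boundary, so "alcohol-craving" contains the whole-token form "craving".
    """
    if not lexicon.terms:
        raise ValueError("cannot compile an empty lexicon")
    forms: set[str] = set()
    for term in lexicon.terms:
        forms |= word_forms(term)
    alternation = "|".join(sorted(forms, key=lambda f: (-len(f), f)))
    regex = re.compile(rf"\b(?:{alternation})\b", re.IGNORECASE)
    return WordFormPattern(lexicon_name=lexicon.name, forms=frozenset(forms), regex=regex)


def expand_lexicon(
    model: EmbeddingModel,
    seeds: Sequence[str] = SEED_TERMS,
    k: int = 10,
    min_score: float = 0.35,
    allowlist: Optional[frozenset] = None,
) -> Lexicon:
    """Grow a lexicon with each seed's top-k embedding neighbors above min_score.

    ``allowlist`` models manual curation: when given, only expansion terms
    inside it survive.  Out-of-vocabulary seeds are kept in the lexicon but
    flagged; if every seed is out of vocabulary the expansion is fatal.
    """
    seeds = tuple(dict.fromkeys(s.lower() for s in seeds))
    oov = tuple(s for s in seeds if s not in model.vocab)
    if len(oov) == len(seeds):
        raise ValueError("all seed terms are out of vocabulary")
    expansion: dict[str, None] = {}
    if k > 0:
        for s in seeds:
            if s in oov:
                continue
            for term, score in most_similar(model, s, k):
                if score >= min_score and term not in seeds:
                    expansion[term] = None
    expanded = tuple(t for t in expansion if allowlist is None or t in allowlist)
    return Lexicon(
        name="craving",
        seed_terms=seeds,
        expanded_terms=expanded,
        curated=allowlist is not None,
        oov_seeds=oov,
    )


@dataclass
class FilterResult:
    craving_posts: list[Post]
    n_total: int

    @property
    def rate(self) -> float:
        """Retrieved fraction; 0.0 (flagged by n_total == 0) on an empty corpus."""
        return len(self.craving_posts) / self.n_total if self.n_total else 0.0


def filter_corpus(corpus, pattern: WordFormPattern) -> FilterResult:
    """Select posts with at least one lexicon match over title+body."""
    posts = corpus.posts if isinstance(corpus, CleanCorpus) else list(corpus)
    subset = [p for p in posts if pattern.matches(p.text)]
    return FilterResult(craving_posts=subset, n_total=len(posts))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalResult:
    confusion: ConfusionMatrix
    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]


def _ratio(num: int, den: int) -> Optional[float]:
    # rational arithmetic, then round: 24/29 -> 0.8276 exactly as printed
    if den == 0:
        return None
    return round(float(Fraction(num, den)), 4)


def evaluate(predictions: Mapping[str, bool], labels: Iterable[LabeledPost]) -> EvalResult:
    """Score binary craving predictions against a labeled test set.

    Undefined ratios (zero denominators) are reported as None, never 0.
    Every labeled post id must have a prediction.
    """
    tp = fp = fn = tn = 0
    for lab in labels:
        if lab.post_id not in predictions:
            raise ValueError(f"no prediction for labeled post {lab.post_id!r}")
        pred = bool(predictions[lab.post_id])
        if pred and lab.craving_label:
            tp += 1
        elif pred and not lab.craving_label:
            fp += 1
        elif not pred and lab.craving_label:
            fn += 1
        else:
            tn += 1
    cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
    return EvalResult(
        confusion=cm,
        accuracy=_ratio(tp + tn, cm.n),
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
    )
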