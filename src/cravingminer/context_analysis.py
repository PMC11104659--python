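"""Craving-context quantification and temporal / sobriety-badge structure.

Contexts (locations, social company, emotions) are detected with curated
term lists matched at word boundaries; the default registry ships the 21
curated category lists used for forum craving posts.  Counting is per
author: each author's craving posts are concatenated into one document so a
category is counted once per distinct user.  Temporal analysis bins posts
by local hour / weekday / month, and the sobriety-badge (flair) histogram
is fit with an exponential decay, excluding the milestone days (one month,
100 days, one year) on which posting spikes.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .corpus_io import LabeledPost, Post
from .craving_filter import EvalResult, evaluate as _evaluate_binary
from .craving_filter import word_forms

__all__ = [
    "ContextQuery",
    "AuthorDocument",
    "ContextReport",
    "TemporalProfile",
    "DecayFit",
    "load_default_registry",
    "load_registry_csv",
    "group_by_author",
    "match_contexts",
    "author_percentages",
    "evaluate_contexts",
    "temporal_profile",
    "flair_decay_fit",
]

GROUPS = ("social", "location", "emotion", "time", "substance")
DEFAULT_FIT_EXCLUDED_DAYS = frozenset({30, 31, 100, 365, 366})


@dataclass(frozen=True)
class ContextQuery:
    category: str
    group: str
    terms: tuple

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if any(t != t.lower() for t in self.terms):
            raise ValueError("context terms must be lowercase")


def _term_regex(term: str, mode: str) -> str:
    words = term.split()
    if mode == "exact_word":
        parts = [re.escape(w) for w in words]
    elif mode == "affix":
        parts = [
            "(?:%s)" % "|".join(sorted(word_forms(w), key=lambda f: (-len(f), f)))
            for w in words
        ]
    else:
        raise ValueError(f"unknown pattern_mode {mode!r}")
    return r"\W+".join(parts)  # multiword terms match as adjacent tokens


def compile_registry(queries: Sequence[ContextQuery], mode: str = "exact_word"):
    """Compile each category's term list into one boundary-aware regex."""
    compiled = {}
    for q in queries:
        alternation = "|".join(_term_regex(t, mode) for t in q.terms)
        compiled[q.category] = re.compile(rf"\b(?:{alternation})\b", re.IGNORECASE)
    return compiled


def _parse_registry(text: str) -> list[ContextQuery]:
    out = []
    for row in csv.DictReader(io.StringIO(text)):
        terms = tuple(t.strip() for t in row["terms"].split(";") if t.strip())
        out.append(ContextQuery(category=row["category"], group=row["group"], terms=terms))
    return out


def load_registry_csv(path) -> list[ContextQuery]:
    with open(path, encoding="utf-8") as fh:
        return _parse_registry(fh.read())


def load_default_registry(extra: bool = False) -> list[ContextQuery]:
    """The 21 curated context term lists (plus, optionally, this package's
    own substance/mental-health extension lists)."""
    data = resources.files("cravingminer.data")
    queries = _parse_registry(data.joinpath("context_registry.csv").read_text("utf-8"))
    if extra:
        queries += _parse_registry(data.joinpath("context_registry_extra.csv").read_text("utf-8"))
    return queries


# ---------------------------------------------------------------------------
# Author grouping


@dataclass
class AuthorDocument:
    author: str
    text: str
    post_count: int
    first_utc: int
    last_utc: int


def group_by_author(posts: Iterable[Post]) -> list[AuthorDocument]:
    """One concatenated document per distinct author, posts in ascending time."""
    by_author: dict[str, list[Post]] = {}
    for p in posts:
        by_author.setdefault(p.author, []).append(p)
    docs = []
    for author in sorted(by_author):
        ps = sorted(by_author[author], key=lambda p: (p.created_utc, p.id))
        docs.append(
            AuthorDocument(
                author=author,
                text=" ".join(p.text for p in ps),
                post_count=len(ps),
                first_utc=ps[0].created_utc,
                last_utc=ps[-1].created_utc,
            )
        )
    return docs


def match_contexts(
    doc,
    registry: Sequence[ContextQuery],
    pattern_mode: str = "exact_word",
    _compiled=None,
) -> set:
    """Categories with at least one term match in the document, at word boundaries."""
    if not registry:
        raise ValueError("registry must be nonempty")
    compiled = _compiled if _compiled is not None else compile_registry(registry, pattern_mode)
    text = doc.text if hasattr(doc, "text") else str(doc)
    return {cat for cat, rx in compiled.items() if rx.search(text)}


@dataclass
class ContextReport:
    total_authors: int
    rows: pd.DataFrame  # columns: group, category, matched_authors, pct_authors

    def percentage(self, category: str) -> float:
        sel = self.rows.loc[self.rows["category"] == category, "pct_authors"]
        if sel.empty:
            raise KeyError(category)
        return float(sel.iloc[0])


def author_percentages(
    docs: Sequence[AuthorDocument],
    registry: Sequence[ContextQuery],
    pattern_mode: str = "exact_word",
) -> ContextReport:
    """Per-category percentage of authors whose concatenated posts match."""
    if not docs:
        raise ValueError("need at least one author document")
    compiled = compile_registry(registry, pattern_mode)
    counts = dict.fromkeys(compiled, 0)
    for doc in docs:
        for cat in match_contexts(doc, registry, pattern_mode, _compiled=compiled):
            counts[cat] += 1
    n = len(docs)
    rows = pd.DataFrame(
        [
            {
                "group": q.group,
                "category": q.category,
                "matched_authors": counts[q.category],
                "pct_authors": round(100.0 * counts[q.category] / n, 2),
            }
            for q in registry
        ]
    )
    return ContextReport(total_authors=n, rows=rows)


def evaluate_contexts(
    predicted: Mapping[str, set],
    labels: Sequence[LabeledPost],
    categories: Optional[Sequence[str]] = None,
) -> dict[str, EvalResult]:
    """Score multi-label context predictions, one independent binary problem
    per category at post level."""
    if categories is None:
        cats: set = set()
        for lab in labels:
            cats |= set(lab.context_labels)
        for v in predicted.values():
            cats |= set(v)
        categories = sorted(cats)
    out: dict[str, EvalResult] = {}
    for cat in categories:
        preds = {}
        cat_labels = []
        for lab in labels:
            if lab.post_id not in predicted:
                raise ValueError(f"no prediction for labeled post {lab.post_id!r}")
            preds[lab.post_id] = cat in predicted[lab.post_id]
            cat_labels.append(
                LabeledPost(post_id=lab.post_id, craving_label=cat in lab.context_labels)
            )
        out[cat] = _evaluate_binary(preds, cat_labels)
    return out


# ---------------------------------------------------------------------------
# Temporal structure


@dataclass
class TemporalProfile:
    hour_hist: np.ndarray  # 24 bins, local hour of day
    weekday_hist: np.ndarray  # 7 bins, Monday=0
    month_hist: np.ndarray  # 12 bins, January=0
    flair_hist: dict[int, int] = field(default_factory=dict)
    missing_offset: int = 0
    n_posts: int = 0


def temporal_profile(posts: Iterable[Post]) -> TemporalProfile:
    """Bin posts by local hour/weekday/month and sobriety-badge day count.

    Local time shifts created_utc by utc_offset_minutes when present; posts
    without an offset are binned in UTC and counted as offset-missing.
    """
    hours = np.zeros(24, dtype=np.int64)
    weekdays = np.zeros(7, dtype=np.int64)
    months = np.zeros(12, dtype=np.int64)
    flair: dict[int, int] = {}
    missing = 0
    n = 0
    for p in posts:
        n += 1
        if p.utc_offset_minutes is None:
            missing += 1
            ts = p.created_utc
        else:
            ts = p.created_utc + 60 * p.utc_offset_minutes
        dt = datetime.fromtimestamp(ts, tz=timezone.utc)
        hours[dt.hour] += 1
        weekdays[dt.weekday()] += 1
        months[dt.month - 1] += 1
        if p.flair_days is not None:
            flair[p.flair_days] = flair.get(p.flair_days, 0) + 1
    return TemporalProfile(
        hour_hist=hours,
        weekday_hist=weekdays,
        month_hist=months,
        flair_hist=flair,
        missing_offset=missing,
        n_posts=n,
    )


@dataclass(frozen=True)
class DecayFit:
    decay_rate: float  # lambda in count(d) ~ c * exp(-lambda * d)
    r_squared: float
    n_bins: int


def flair_decay_fit(
    profile: TemporalProfile,
    milestones: frozenset = DEFAULT_FIT_EXCLUDED_DAYS,
) -> DecayFit:
    """Exponential-decay fit of the sobriety-badge histogram.

    Least-squares of log(count) on day over day bins with count > 0,
    excluding milestone days whose spikes would bias the rate.  Bins are
    inverse-variance weighted: Var(log c) ~ 1/c for Poisson counts, so each
    bin enters with weight c — equivalently one IRLS step of the log-linear
    Poisson regression.  Without the weighting, near-empty tail bins
    (count 1-2, floored at zero on the log scale) flatten the slope.  For
    exact geometric counts c*q^d the recovered rate is -log(q).
    """
    days = np.array(
        sorted(d for d, c in profile.flair_hist.items() if c > 0 and d not in milestones),
        dtype=np.float64,
    )
    if days.size < 10:
        raise ValueError(f"need >= 10 distinct non-milestone flair days, have {days.size}")
    counts = np.array([profile.flair_hist[int(d)] for d in days], dtype=np.float64)
    logc = np.log(counts)
    slope, intercept = np.polyfit(days, logc, 1, w=np.sqrt(counts))
    pred = slope * days + intercept
    ss_res = float(np.sum((logc - pred) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(decay_rate=-float(slope), r_squared=r2, n_bins=int(days.size))


def flair_days_to_years(days: int) -> float:
    """Convert a sobriety-badge day count to years (365.25-day years)."""
    return days / 365.25


def weekday_weekend_shares(profile: TemporalProfile) -> dict[str, float]:
    """Fraction of posts on weekdays vs the weekend (local time)."""
    total = int(profile.weekday_hist.sum())
    weekend = int(profile.weekday_hist[5] + profile.weekday_hist[6])
    if total == 0:
        return {"weekday": 0.0, "weekend": 0.0}
    return {"weekday": (total - weekend) / total, "weekend": weekend / total}
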