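"""Reading, cleaning and encoding of forum corpora.

The on-disk corpus dialect is JSON Lines with one submission record per
line, mirroring Pushshift submission dumps: ``id``, ``author``, ``title``,
``selftext``, ``created_utc``, ``author_flair_text`` and the optional
extension field ``utc_offset_minutes``.  Cleaning removes deleted posts and
posts shorter than 60 characters; preprocessing lowercases, tokenizes,
lemmatizes (deterministic suffix-stripping rule table shipped with the
package) and drops stopwords, producing the token documents consumed by the
embedding and topic-model stages.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Post",
    "CleanCorpus",
    "TokenDoc",
    "Vocabulary",
    "BOWCorpus",
    "LabeledPost",
    "ReadResult",
    "read_posts",
    "write_posts",
    "parse_flair_days",
    "clean",
    "load_stopwords",
    "load_lemma_rules",
    "lemmatize",
    "tokenize",
    "preprocess",
    "build_bow",
    "read_labels",
    "write_labels",
    "registered_categories",
]

DELETED_SENTINELS = frozenset({"[deleted]", "[removed]"})
MIN_POST_CHARS = 60


@dataclass(frozen=True)
class Post:
    """One forum submission."""

    id: str
    author: str
    title: str = ""
    body: str = ""
    created_utc: int = 0
    utc_offset_minutes: Optional[int] = None
    flair_days: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("post id must be nonempty")
        if self.created_utc < 0:
            raise ValueError("created_utc must be >= 0")
        if self.flair_days is not None and self.flair_days < 0:
            raise ValueError("flair_days must be >= 0 when present")

    @property
    def text(self) -> str:
        """Combined title + body used by every downstream stage."""
        return f"{self.title} {self.body}".strip() if self.title else self.body


@dataclass
class CleanCorpus:
    posts: list[Post]
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self):
        return iter(self.posts)


@dataclass
class TokenDoc:
    post_id: str
    tokens: list[str]


@dataclass(frozen=True)
class LabeledPost:
    post_id: str
    craving_label: bool
    context_labels: frozenset = frozenset()


@dataclass
class ReadResult:
    posts: list[Post]
    skipped: int = 0

    def __iter__(self):
        return iter(self.posts)

    def __len__(self) -> int:
        return len(self.posts)


class Vocabulary:
    """Bijection between terms and contiguous indices, with document frequencies."""

    def __init__(self, terms: Sequence[str], doc_freq: Optional[np.ndarray] = None):
        self.id2term: list[str] = list(terms)
        self.term2id: dict[str, int] = {t: i for i, t in enumerate(self.id2term)}
        if len(self.term2id) != len(self.id2term):
            raise ValueError("duplicate terms in vocabulary")
        self.doc_freq = (
            np.asarray(doc_freq, dtype=np.int64)
            if doc_freq is not None
            else np.zeros(len(self.id2term), dtype=np.int64)
        )

    def __len__(self) -> int:
        return len(self.id2term)

    def __contains__(self, term: str) -> bool:
        return term in self.term2id

    def __getitem__(self, term: str) -> int:
        return self.term2id[term]


@dataclass
class BOWCorpus:
    """Sparse document-term counts over a shared vocabulary."""

    vocab: Vocabulary
    matrix: sp.csr_matrix  # D x V, nonnegative integer counts
    doc_ids: list[str]

    @property
    def n_docs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_tokens(self) -> int:
        return int(self.matrix.sum())


# ---------------------------------------------------------------------------
# Reading / writing posts


def parse_flair_days(flair_text: Optional[str]) -> Optional[int]:
    """Extract the sobriety-badge day count from an author flair string.

    Recognized templates are ``"<int> day(s)"`` (thousands separators
    allowed, e.g. ``"14,662 days"``) and a bare integer.  Anything else —
    including ``None`` and the empty string — yields ``None``.
    """
    if not flair_text:
        return None
    m = re.fullmatch(r"\s*(\d[\d,]*)\s*(?:days?)?\s*", flair_text, re.IGNORECASE)
    if not m:
        return None
    return int(m.group(1).replace(",", ""))


def _post_from_record(rec: Mapping) -> Post:
    created = int(rec.get("created_utc", 0))
    offset = rec.get("utc_offset_minutes")
    return Post(
        id=str(rec["id"]),
        author=str(rec.get("author", "")),
        title=str(rec.get("title", "") or ""),
        body=str(rec.get("selftext", "") or ""),
        created_utc=created,
        utc_offset_minutes=int(offset) if offset is not None else None,
        flair_days=parse_flair_days(rec.get("author_flair_text")),
    )


def read_posts(path, dialect: str = "pushshift_jsonl") -> ReadResult:
    """Read posts from a JSON-Lines file; malformed lines are skipped and counted."""
    if dialect != "pushshift_jsonl":
        raise ValueError(f"unknown dialect: {dialect!r}")
    posts: list[Post] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                posts.append(_post_from_record(rec))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                skipped += 1
    if not posts:
        raise ValueError(f"no parseable records in {path}")
    return ReadResult(posts=posts, skipped=skipped)


def write_posts(posts: Iterable[Post], path) -> None:
    """Write posts in the same JSON-Lines dialect that :func:`read_posts` accepts."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            rec = {
                "id": p.id,
                "author": p.author,
                "title": p.title,
                "selftext": p.body,
                "created_utc": p.created_utc,
                "author_flair_text": f"{p.flair_days} days" if p.flair_days is not None else None,
            }
            if p.utc_offset_minutes is not None:
                rec["utc_offset_minutes"] = p.utc_offset_minutes
            fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# Cleaning


def clean(posts: Iterable[Post]) -> CleanCorpus:
    """Drop deleted posts and posts whose combined title+body is under 60 chars.

    The length rule counts characters of the raw combined text, before any
    tokenization.  Cleaning is idempotent.
    """
    kept: list[Post] = []
    prov = {"deleted": 0, "too_short": 0, "kept": 0}
    for p in posts:
        if p.body.strip().lower() in DELETED_SENTINELS:
            prov["deleted"] += 1
        elif len(p.text) < MIN_POST_CHARS:
            prov["too_short"] += 1
        else:
            kept.append(p)
            prov["kept"] += 1
    return CleanCorpus(posts=kept, provenance=prov)


# ---------------------------------------------------------------------------
# Preprocessing

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_VOWELS = "aeiou"


def load_stopwords() -> frozenset:
    text = resources.files("cravingminer.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(
        w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")
    )


def load_lemma_rules():
    """Parse the shipped rule table into (keep_set, rules).

    Each rule is ``(suffix, replacement, min_stem_len, flag)``.
    """
    text = resources.files("cravingminer.data").joinpath("lemma_rules.tsv").read_text("utf-8")
    keep: set[str] = set()
    rules: list[tuple[str, str, int, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "keep":
            keep.add(parts[1])
        elif parts[0] == "rule":
            suffix, repl, min_len = parts[1], parts[2], int(parts[3])
            flag = parts[4] if len(parts) > 4 else ""
            rules.append((suffix, "" if repl == "-" else repl, min_len, flag))
    return frozenset(keep), tuple(rules)


_DEFAULT_LEMMA = None


def _default_lemma_table():
    global _DEFAULT_LEMMA
    if _DEFAULT_LEMMA is None:
        _DEFAULT_LEMMA = load_lemma_rules()
    return _DEFAULT_LEMMA


def lemmatize(token: str, table=None) -> str:
    """Apply the first matching suffix rule, once; keep-listed words pass through."""
    keep, rules = table if table is not None else _default_lemma_table()
    if token in keep:
        return token
    for suffix, repl, min_len, flag in rules:
        if not token.endswith(suffix):
            continue
        stem = token[: len(token) - len(suffix)]
        if len(stem) < min_len:
            continue
        if flag == "sibilant" and not stem.endswith(("s", "x", "z", "ch", "sh")):
            continue
        if flag == "nosui" and token.endswith(("ss", "us", "is")):
            continue
        stem += repl
        if flag == "undouble" and len(stem) >= 2 and stem[-1] == stem[-2]:
            if stem[-1] not in _VOWELS and stem[-1] not in "lsfz":
                stem = stem[:-1]
        return stem
    return token


def tokenize(text: str) -> list[str]:
    """Lowercase and split on any non-alphanumeric character; keep tokens of length >= 2."""
    return [t for t in _TOKEN_RE.findall(text.lower()) if len(t) >= 2]


def _join_phrases(tokens: list[str], phrases: Sequence[tuple]) -> list[str]:
    if not phrases:
        return tokens
    # longest-first so e.g. a 3-gram wins over an embedded 2-gram
    by_len = sorted(phrases, key=len, reverse=True)
    out: list[str] = []
    i = 0
    while i < len(tokens):
        matched = False
        for ph in by_len:
            n = len(ph)
            if n > 1 and tuple(tokens[i : i + n]) == tuple(ph):
                out.append("_".join(ph))
                i += n
                matched = True
                break
        if not matched:
            out.append(tokens[i])
            i += 1
    return out


def preprocess(
    post,
    stopwords: Optional[frozenset] = None,
    lemma_table=None,
    phrases: Sequence[tuple] = (),
) -> TokenDoc:
    """Turn a post (or raw string) into a lowercase, lemmatized, stopword-free TokenDoc.

    ``phrases`` is a sequence of token tuples (e.g. ``("living", "room")``)
    joined into single underscore tokens before lemmatization, so that
    multiword lexicon terms survive as one vocabulary entry.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    if isinstance(post, str):
        post_id, text = "", post
    else:
        post_id, text = post.id, post.text
    toks = _join_phrases(tokenize(text), phrases)
    out = []
    for t in toks:
        if "_" not in t:
            t = lemmatize(t, lemma_table)
        if t not in stopwords and len(t) >= 2:
            out.append(t)
    return TokenDoc(post_id=post_id, tokens=out)


def preprocess_corpus(posts: Iterable[Post], **kw) -> list[TokenDoc]:
    """Convenience wrapper: preprocess every post with a shared stopword set."""
    stop = kw.pop("stopwords", None) or load_stopwords()
    lemma = kw.pop("lemma_table", None) or _default_lemma_table()
    return [preprocess(p, stopwords=stop, lemma_table=lemma, **kw) for p in posts]


# ---------------------------------------------------------------------------
# Bag of words


def build_bow(docs: Sequence[TokenDoc], min_count: int = 2) -> BOWCorpus:
    """Encode token documents as sparse counts over terms with corpus frequency >= min_count."""
    if not any(d.tokens for d in docs):
        raise ValueError("cannot build a bag-of-words model from empty documents")
    freq: dict[str, int] = {}
    for d in docs:
        for t in d.tokens:
            freq[t] = freq.get(t, 0) + 1
    terms = sorted(t for t, c in freq.items() if c >= min_count)
    if not terms:
        raise ValueError(f"vocabulary is empty at min_count={min_count}")
    vocab = Vocabulary(terms)
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    df = np.zeros(len(terms), dtype=np.int64)
    for d in docs:
        counts: dict[int, int] = {}
        for t in d.tokens:
            j = vocab.term2id.get(t)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j in sorted(counts):
            indices.append(j)
            data.append(counts[j])
            df[j] += 1
        indptr.append(len(indices))
    vocab.doc_freq = df
    mat = sp.csr_matrix(
        (np.array(data, dtype=np.int64), np.array(indices, dtype=np.int32), np.array(indptr)),
        shape=(len(docs), len(terms)),
    )
    return BOWCorpus(vocab=vocab, matrix=mat, doc_ids=[d.post_id for d in docs])


# ---------------------------------------------------------------------------
# Labels


def registered_categories(extra: bool = False) -> frozenset:
    """Category names of the default context registry (optionally plus the
    substance/mental-health extension)."""
    from . import context_analysis  # deferred: avoids an import cycle

    queries = context_analysis.load_default_registry(extra=extra)
    return frozenset(q.category for q in queries)


def read_labels(path, categories: Optional[frozenset] = None) -> list[LabeledPost]:
    """Read a labeled test set CSV (post_id, craving_label, context_labels).

    Multi-label context annotations are semicolon-joined.  A context label
    outside the registered categories is fatal.
    """
    if categories is None:
        categories = registered_categories(extra=True)
    out: list[LabeledPost] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            ctx = frozenset(c for c in row.get("context_labels", "").split(";") if c)
            unknown = ctx - categories
            if unknown:
                raise ValueError(f"unregistered context categories: {sorted(unknown)}")
            out.append(
                LabeledPost(
                    post_id=row["post_id"],
                    craving_label=row["craving_label"].strip() in {"1", "True", "true"},
                    context_labels=ctx,
                )
            )
    return out


def write_labels(labels: Iterable[LabeledPost], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["post_id", "craving_label", "context_labels"])
        for lab in labels:
            w.writerow(
                [lab.post_id, int(lab.craving_label), ";".join(sorted(lab.context_labels))]
            )
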