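# Methods

This note documents the models and procedures implemented in
`cravingminer`, the parameters that matter, the design choices made where
the design was genuinely open, and the limits of what the synthetic-data
tests establish.

## Corpus model and cleaning

A post is a forum submission: `id`, `author`, `title`, `body`,
`created_utc`, an optional `utc_offset_minutes` (minutes to add to UTC to
obtain the author's local time), and an optional `flair_days` sobriety
badge parsed from the author-flair string. Badge parsing accepts
`"<int> day(s)"` with optional thousands separators, or a bare integer;
anything else yields "absent" rather than an error, since flair strings
are free text.

Cleaning drops posts whose body is a deletion sentinel (`[deleted]` /
`[removed]`, case-insensitive — the Pushshift convention) and posts whose
combined raw `title + " " + body` is under 60 characters. The length rule
counts raw characters, before tokenization, because the unit being
filtered is the post, not its token stream. Titles are included in the
analyzed text throughout: forum titles routinely carry the craving mention
itself. Cleaning is idempotent by construction.

### Preprocessing

Lowercase; split on any non-alphanumeric character; keep tokens of length
≥ 2 (the token `711` — a convenience-store name appearing in a context
list — is numeric and passes naturally). Lemmatization is a deterministic
suffix-stripping rule table shipped with the package
(`data/lemma_rules.tsv`): plural `-ies/-es/-s`, then `-ing`/`-ed` with
undoubling of a doubled final consonant (never for `ll/ss/ff/zz`, so
`falling → fall`, `stopped → stop`). A keep-list protects lexicalized
`-ing` nouns (`craving`, `feeling`, `meeting`, `morning`, ...) from being
truncated to nonsense stems. The stopword list (~150 entries) is shipped
and versioned in-repo for reproducibility, and deliberately excludes every
term used by the context registry or craving lexicon (`alone`, `ex`,
`bed`, ...). This is a stand-in for an external lemmatizer/stopword stack:
fully testable, no model downloads, and adequate for the statistical
analyses in scope — it does not attempt general-purpose English
lemmatization.

Multiword lexicon terms (the registry contains the bigram `living room`)
are pre-joined into single underscore tokens during preprocessing when a
phrase list is supplied, so they survive as one vocabulary entry for
embedding queries.

## Synthetic corpus generator

The generator emulates the statistical structure of a sobriety-forum
craving corpus so that every pipeline stage has exact ground truth. Its
defaults are the study conditions the pipeline is designed around:

| parameter | default | meaning |
| --- | --- | --- |
| `single_post_author_fraction` | 0.70 | P(author writes exactly one post) |
| post-count law | `1 + Geom(1/2)` for multi-post authors | gives ≈15% two-post authors |
| `mean_post_words` | 105 | Poisson post length |
| `craving_rate` | 0.16 | per-post craving probability |
| `context_rates` | per category, 0.02–0.50 | per-author context injection probability |
| `diurnal_peak_window`, `diurnal_peak_ratio` | 13–23 h, 3 | local-time posting intensity |
| `flair_decay_rate` | 0.02 | geometric badge-day parameter p |
| `milestone_days`, `milestone_boost` | {30, 100, 365}, 8 | posting spikes on milestones |

Filler text is drawn from an LDA generative model over an artificial
vocabulary (`w000`, ...), so one corpus serves both the filter tests and
topic-recovery tests. Craving posts receive one seed-lexicon term as stem,
`+s`, `+ing` (with `e`-elision) or an `alcohol-` compound, exercising the
word-form pattern rules. Context injection is per author and per category;
only terms belonging to exactly one category are injected (e.g. `wife`,
which the family and partner lists share by design, is never injected), so
every planted per-category rate is an exact binomial and recovery can be
tested against exact 99% intervals. Timestamps are sampled in local time
from the diurnal intensity and carry the author's UTC offset, which makes
the local-time analysis well-defined. Badge days are sampled from a
geometric law with milestone mass multiplied by `milestone_boost`; since
the boost rescales only milestone bins, the decay fit (which excludes
them) is invariant to it. Author-level randomness is keyed by
`(seed, author index)`, so corpora are prefix-stable under changes of
`n_authors`.

What the generator does **not** emulate: grammar, discourse, paraphrase,
sarcasm, ambiguous craving mentions, lexical collisions between craving
vocabulary and ordinary text. Passing recovery tests therefore establishes
that the machinery is correct under the stated statistical assumptions —
not that the lexicons are complete or the contexts exhaustive on real
forum text, where precision/recall are strictly worse.

## Word embeddings

Skip-gram with negative sampling, re-implemented (the analysis needs only
similarity queries, and a from-scratch trainer keeps runs bit-reproducible):
fixed context window, unigram^0.75 negative-sampling table, sigmoid
updates on input/output vector pairs, learning rate decaying linearly over
processed centers to `lr·1e-4`. Training is single-threaded with an
internal xorshift64* generator, so a seed fixes the vectors exactly.
Subsampling of frequent words is omitted: it adds nondeterminism and
matters only at corpus scales far beyond these analyses. Similarity is
cosine over **input** vectors (the common convention; fixed for
reproducibility), reported as percentages rounded to two decimals in
reports. Nearest-neighbor queries exclude the query term and break score
ties lexicographically. Defaults: `dim=100`, `window=5`, `negatives=5`,
`epochs=5`, `min_count=5`.

Embedding quality is asserted distributionally: tokens planted in
interchangeable contexts must score above the 95th percentile of random
background-pair cosine. On small corpora all cosines are high
(anisotropy), which is why the test compares against the random-pair
distribution rather than an absolute threshold.

## Craving lexicon and word-form pattern

Seeds: `craving`, `trigger`, `relapse`, `urge`, `desire`, `temptation`.
Expansion takes each seed's top-`k` neighbors (`k=10`,
`min_score=0.35` by default) and intersects with an allowlist when manual
curation is wanted; out-of-vocabulary seeds are kept but flagged, and only
an entirely out-of-vocabulary seed set is fatal.

The pattern matches a whole token of the form `prefix + stem + suffix`
with curated affix inventories (prefixes `un re de non dis mis pre anti
over under`; suffixes `s es ed d ing ings er ers or ors ion ions ive ives
y al ally able ful less ness ment ments`), with the stem's final `e`
elided before vowel-initial suffixes (`urge → urging`), plus
hyphen-compound membership (`alcohol-craving`; a hyphen is a word
boundary, so compound components match naturally). The affix inventory —
rather than "any short character run" — is what guarantees the
word-boundary contract: `barely` can never match a stem `bar`, while
`cravings`, `triggered` and `relapsing` all match. Zero-derivation
("conversion") pairs are covered to the extent the affix table and the
lemma rules overlap; POS tagging is deliberately out of scope. All forms
are enumerated at compile time into one case-insensitive alternation, so
matching is a single regex scan per post.

Evaluation ratios are computed in rational arithmetic and rounded to four
decimals, so the canonical worked example (200 posts, 29 predicted / 41
labeled positive, 24 correct → accuracy 0.89, precision 0.8276, recall
0.5854) reproduces digit-for-digit. Undefined ratios (empty denominators)
are reported as absent, never as 0.

## Context analysis

The default registry ships 21 curated term lists over three groups
(8 locations, 8 emotions, 5 social categories); lists may overlap (`wife`
⇒ both family and partner — intended multi-labeling). Matching is
exact-word at word boundaries by default: the lists already enumerate the
inflections they intend (`working`, `worked`), and affix mode (available
as an option) would over-match short terms such as `ex`. Multiword terms
match as adjacent tokens across any non-word separator. Author
percentages are computed on per-author concatenated documents (a category
counts distinct users); test-set evaluation is per post, each category
scored as an independent binary problem. A substance/mental-health
extension registry (nicotine, depression, anxiety lists of this package's
own choosing) is shipped separately and off by default.

Temporal profiles bin by local hour/weekday/month, shifting by the post's
UTC offset when present and counting offset-missing posts explicitly
(UTC is used for them). The badge-decay fit regresses `log count` on day
over bins with `count > 0`, excluding milestone bins
({30, 31, 100, 365, 366} by default — the day-after bins absorb spillover),
with inverse-variance weights: `Var(log c) ≈ 1/c` for Poisson counts, so
each bin enters with classical weight `c`, equivalently one IRLS step of
the log-linear Poisson regression. Unweighted least squares is biased low
(~15% at the 20k-author recovery condition) because near-empty tail bins
are floored at `log c = 0` and flatten the slope; the weighted fit
recovers the planted rate within 10% and is insensitive to milestone
boosts. On noiseless geometric counts the fit is exact.

## Topic model

Collapsed Gibbs sampling with the standard conditional
`p(z_i=k) ∝ (n_dk+α)(n_kw+β)/(n_k+Vβ)`; `φ` and `θ` are smoothed
estimates averaged over post-burn-in samples (defaults: 500 iterations,
300 burn-in, thinning 10; `α = 50/K`, `β = 0.01` for single fits). The
sampler is a compiled single-threaded kernel with its own seeded
generator: identical corpus + config ⇒ identical assignments. Count
matrices are returned for conservation checks (`Σ_k n_kw` equals the
corpus count of `w`). Empty documents are tolerated (uniform `θ` row);
an empty corpus is fatal.

Validation perplexity uses **document completion**: each held-out
document's tokens are split alternately into an estimation half (on which
`θ'` is folded in by Gibbs sampling with `φ` fixed) and a scoring half
(on which `exp(−Σ log Σ_k θ'_k φ_kw / N)` is evaluated). Folding in on
the scored tokens themselves lets every extra topic improve the per-document
fit, which drags the perplexity minimum above the true K; with completion
(and a shared fixed `α` across candidates — the `50/K` heuristic likewise
hands larger K extra smoothing) the minimum lands at the generative K
robustly across fixed `(α, β)` choices. `select_num_topics` therefore
defaults to `α = 0.1` for the sweep and picks the lowest validation
perplexity, with coherence as tiebreaker. With uniform `φ` the perplexity
equals `V` exactly, a closed-form check.

NPMI coherence uses document-level co-occurrence (the corpus is bag-of-
words; no sliding window exists): `p(w) = df(w)/D`,
`p_ij = df(w_i ∧ w_j)/D + ε` with `ε = 1e-12` applied to the joint only,
so exactly independent pairs score 0 (to within `ε`-noise ≪ 1e-9) and
never-co-occurring pairs stay finite near −1. A pair that is ubiquitous
(`p_i = p_j = p_ij = 1`) has PMI 0 and is scored 0. Pairs involving words
absent from the reference corpus are skipped. Topic summaries report the
top-12 words per topic (ties lexicographic), per-topic coherence sorted
decreasing, and a vocabulary share: each word is assigned to its argmax
topic (ties to the lowest index), so shares partition 100%.

## Pipeline

Stages communicate via files only (JSONL corpora, CSV reports, a
two-file embedding model), each stage independently runnable. The flat
`key = value` config is validated against the full key list before any
stage runs. Lexicon expansion is **off** by default in the pipeline: on
its own, nearest-neighbor expansion needs the manual curation step the
workflow assumes, and uncurated neighbors inflate retrieval. Each run
writes a manifest (versions, seed, config, SHA-256 digests of artifacts);
a rerun with the same seed and config is byte-identical.

## Problem sizes and numerical choices

Recovery tests use sizes at which the asserted intervals are sharp but
runs stay cheap: 5000 authors (≈8000 posts) for rate/context recovery
against exact binomial 99% intervals; 20 000 authors for the decay fit
(text shortened to 20 words there — the badge analysis never reads it);
`K=5, V=200, D=1000, 80 tokens/doc` over 5 seeds for topic recovery
(greedy-matched mean cosine ≥ 0.8) and K selection from {2, 5, 10}; 10
seeds for embedding-synonym recovery. Statistical acceptance tests are
derandomized with fixed seeds chosen up front; each 99%-interval
assertion has the corresponding per-draw false-alarm probability by
construction.

## Known limitations

- The lemmatizer and stopword list are deliberate simplifications; real
  English coverage (irregular forms, `-e` restoration: `making → mak`) is
  out of scope and irrelevant to the synthetic analyses.
- The affix inventory is curated, not exhaustive (`desirable` does not
  match `desire`); extending it is a data-file edit.
- Context percentages are co-occurrence rates, not causal trigger
  prevalences.
- Real-corpus quantities (retrieval rates, context percentages, coherence
  magnitudes) depend on the corpus and on hyperparameters that published
  analyses typically leave unstated; this package asserts its own
  machinery on ground-truth corpora instead.
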