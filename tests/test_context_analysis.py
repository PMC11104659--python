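"""Context matching, author grouping, temporal and sobriety-badge analysis."""

import math

import numpy as np
import pytest
from scipy import stats

from cravingminer import context_analysis as ca
from cravingminer import synthetic_data as sd
from cravingminer.corpus_io import LabeledPost, Post


@pytest.fixture(scope="module")
def registry():
    return ca.load_default_registry()


class TestRegistry:
    def test_twenty_one_categories(self, registry):
        assert len(registry) == 21
        assert len({q.category for q in registry}) == 21

    def test_groups_partition(self, registry):
        groups = {q.group for q in registry}
        assert groups == {"location", "emotion", "social"}

    def test_known_terms_present(self, registry):
        by_cat = {q.category: q.terms for q in registry}
        assert "living room" in by_cat["home"]
        assert "wife" in by_cat["family"] and "wife" in by_cat["partner"]
        assert "711" in by_cat["supermarket"]


class TestGroupByAuthor:
    def test_distinct_authors(self):
        posts = [
            Post(id="a", author="u1", body="x", created_utc=1),
            Post(id="b", author="u2", body="y", created_utc=2),
            Post(id="c", author="u1", body="z", created_utc=3),
        ]
        docs = ca.group_by_author(posts)
        assert len(docs) == 2

    def test_concatenation_in_time_order(self):
        posts = [
            Post(id="late", author="u", body="second", created_utc=2),
            Post(id="early", author="u", body="first", created_utc=1),
        ]
        doc = ca.group_by_author(posts)[0]
        assert doc.text == "first second"
        assert doc.first_utc == 1 and doc.last_utc == 2

    def test_post_count_conservation(self, small_corpus):
        posts, _ = small_corpus
        docs = ca.group_by_author(posts)
        assert sum(d.post_count for d in docs) == len(posts)

    def test_single_post_fraction_near_planted(self, big_corpus):
        posts, _ = big_corpus
        docs = ca.group_by_author(posts)
        single = sum(1 for d in docs if d.post_count == 1)
        lo, hi = stats.binom.ppf([0.005, 0.995], len(docs), 0.70)
        assert lo <= single <= hi


class TestMatchContexts:
    def test_wife_yields_family_and_partner(self, registry):
        assert ca.match_contexts("my wife was home", registry) == {"family", "partner", "home"}

    def test_word_boundaries(self, registry):
        assert ca.match_contexts("barely awake", registry) == set()

    def test_multiword_term(self, registry):
        assert ca.match_contexts("living room was cold", registry) == {"home"}

    def test_empty_registry_fatal(self):
        with pytest.raises(ValueError):
            ca.match_contexts("text", [])

    def test_wife_documents_always_double_labeled(self, big_corpus, registry):
        """The family/partner lists overlap by construction: any document
        mentioning 'wife' must carry both categories."""
        posts, _ = big_corpus
        checked = 0
        for doc in ca.group_by_author(posts[:4000]):
            text = f"{doc.text} my wife called"
            cats = ca.match_contexts(text, registry)
            assert {"family", "partner"} <= cats
            checked += 1
            if checked >= 50:
                break


class TestAuthorPercentages:
    def test_half_matching(self, registry):
        docs = [
            ca.AuthorDocument("u1", "so bored now", 1, 0, 0),
            ca.AuthorDocument("u2", "feeling bored", 1, 0, 0),
            ca.AuthorDocument("u3", "all fine", 1, 0, 0),
            ca.AuthorDocument("u4", "sunny day", 1, 0, 0),
        ]
        rep = ca.author_percentages(docs, registry)
        assert rep.percentage("bored") == 50.00

    def test_absent_category_zero(self, registry):
        docs = [ca.AuthorDocument("u1", "plain words", 1, 0, 0)]
        rep = ca.author_percentages(docs, registry)
        assert rep.percentage("airport") == 0.00

    def test_bounds_and_counts(self, small_corpus, registry):
        posts, _ = small_corpus
        rep = ca.author_percentages(ca.group_by_author(posts), registry)
        assert ((rep.rows["pct_authors"] >= 0) & (rep.rows["pct_authors"] <= 100)).all()
        assert (rep.rows["matched_authors"] <= rep.total_authors).all()

    def test_planted_rates_recovered(self, big_corpus, registry):
        """All 21 planted per-author context rates inside binomial 99% intervals."""
        posts, truth = big_corpus
        cfg_rates = sd.GeneratorConfig().context_rates
        docs = ca.group_by_author(posts)
        n = len(docs)
        rep = ca.author_percentages(docs, registry)
        for q in registry:
            rate = cfg_rates[q.category]
            matched = int(
                rep.rows.loc[rep.rows["category"] == q.category, "matched_authors"].iloc[0]
            )
            lo, hi = stats.binom.ppf([0.005, 0.995], n, rate)
            assert lo <= matched <= hi, (q.category, matched, lo, hi)


class TestEvaluateContexts:
    def test_perfect_multilabel(self):
        labels = [
            LabeledPost("a", True, frozenset({"home", "work"})),
            LabeledPost("b", False, frozenset({"bored"})),
        ]
        pred = {"a": {"home", "work"}, "b": {"bored"}}
        res = ca.evaluate_contexts(pred, labels)
        for cat in ("home", "work", "bored"):
            assert res[cat].precision == 1.0 and res[cat].recall == 1.0

    def test_absent_category_accuracy_one_ratios_absent(self):
        labels = [LabeledPost("a", True, frozenset())]
        res = ca.evaluate_contexts({"a": set()}, labels, categories=["airport"])
        r = res["airport"]
        assert r.accuracy == 1.0 and r.precision is None and r.recall is None

    def test_injected_contexts_high_recall(self, big_corpus, registry):
        """Exact-word matching must recover essentially all injected labels."""
        posts, truth = big_corpus
        compiled = ca.compile_registry(registry)
        subset = posts[:3000]
        pred = {p.id: {c for c, rx in compiled.items() if rx.search(p.text)} for p in subset}
        labels = [LabeledPost(p.id, truth.craving[p.id], truth.contexts[p.id]) for p in subset]
        res = ca.evaluate_contexts(pred, labels, categories=[q.category for q in registry])
        for cat, r in res.items():
            if r.recall is not None:
                assert r.recall >= 0.95, (cat, r)


class TestTemporalProfile:
    def test_offset_shifts_hour(self):
        p = Post(id="a", author="u", body="x", created_utc=0, utc_offset_minutes=60)
        prof = ca.temporal_profile([p])
        assert prof.hour_hist[1] == 1

    def test_missing_offset_counted(self):
        p = Post(id="a", author="u", body="x", created_utc=0)
        prof = ca.temporal_profile([p])
        assert prof.missing_offset == 1 and prof.hour_hist[0] == 1

    def test_histograms_sum_to_post_count(self, small_corpus):
        posts, _ = small_corpus
        prof = ca.temporal_profile(posts)
        assert prof.hour_hist.sum() == len(posts)
        assert prof.weekday_hist.sum() == len(posts)
        assert prof.month_hist.sum() == len(posts)
        with_flair = sum(1 for p in posts if p.flair_days is not None)
        assert sum(prof.flair_hist.values()) == with_flair

    def test_diurnal_peak(self, big_corpus):
        posts, _ = big_corpus
        prof = ca.temporal_profile(posts)
        assert prof.hour_hist[13:24].sum() / prof.n_posts > 11 / 24


class TestFlairDecayFit:
    def _profile(self, hist):
        z = np.zeros
        return ca.TemporalProfile(z(24, int), z(7, int), z(12, int), hist, 0, 0)

    def test_exact_geometric_closed_form(self):
        # exact integer counts 2^(40-d): lambda must equal log 2 to 1e-9
        prof = self._profile({d: 2 ** (40 - d) for d in range(1, 31)})
        fit = ca.flair_decay_fit(prof)
        assert abs(fit.decay_rate - math.log(2)) < 1e-9
        assert fit.r_squared == pytest.approx(1.0)

    def test_insufficient_bins_error(self):
        prof = self._profile({d: 5 for d in range(1, 8)})
        with pytest.raises(ValueError):
            ca.flair_decay_fit(prof)

    def test_milestone_bins_excluded(self):
        base = {d: 2 ** (40 - d) for d in range(1, 31) if d != 30}
        lam0 = ca.flair_decay_fit(self._profile({**base, 30: 999_999})).decay_rate
        lam1 = ca.flair_decay_fit(self._profile({**base, 30: 10})).decay_rate
        assert lam0 == pytest.approx(lam1, abs=1e-12)


def test_flair_days_to_years():
    assert round(ca.flair_days_to_years(14662)) == 40
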