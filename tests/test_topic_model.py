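"""Collapsed-Gibbs LDA: sampler bookkeeping, recovery, perplexity, coherence."""

import math

import numpy as np
import pytest

from cravingminer import synthetic_data as sd
from cravingminer import topic_model as tm
from cravingminer.corpus_io import TokenDoc, build_bow
from .conftest import greedy_matched_cosine


@pytest.fixture(scope="module")
def fitted(topic_corpus):
    bow, phi_true, theta_true = topic_corpus
    cfg = tm.LDAConfig(K=5, iterations=300, burn_in=200, thin=10, seed=0)
    return tm.fit(bow, cfg), bow, phi_true


class TestFit:
    def test_token_count_conservation(self, fitted):
        model, bow, _ = fitted
        assert np.array_equal(
            model.nkw.sum(axis=0), np.asarray(bow.matrix.sum(axis=0)).ravel()
        )
        assert np.array_equal(
            model.ndk.sum(axis=1), np.asarray(bow.matrix.sum(axis=1)).ravel()
        )

    def test_rows_normalized(self, fitted):
        model, _, _ = fitted
        assert np.allclose(model.phi.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.theta.sum(axis=1), 1.0, atol=1e-9)

    def test_seed_determinism(self, topic_corpus):
        bow, _, _ = topic_corpus
        cfg = tm.LDAConfig(K=3, iterations=30, burn_in=10, thin=5, seed=42)
        m1, m2 = tm.fit(bow, cfg), tm.fit(bow, cfg)
        assert np.array_equal(m1.assignments, m2.assignments)
        assert np.array_equal(m1.phi, m2.phi)

    def test_empty_document_gets_uniform_theta(self):
        docs = [TokenDoc("d0", ["aa", "bb", "aa"]), TokenDoc("d1", [])]
        bow = build_bow(docs, min_count=1)
        model = tm.fit(bow, tm.LDAConfig(K=2, iterations=20, burn_in=10, thin=2, seed=1))
        assert np.allclose(model.theta[1], 0.5)

    def test_empty_corpus_fatal(self):
        bow, _, _ = sd.generate_topic_corpus(K=2, V=10, D=0, doc_len=5, alpha=0.5, beta=0.1)
        with pytest.raises(ValueError):
            tm.fit(bow, tm.LDAConfig(K=2, iterations=10, burn_in=5))

    def test_single_topic_corpus_degenerate_recovery(self):
        """K_true=1 data fit with K=2: one fitted topic must reproduce >= 9
        of the true distribution's top-10 words."""
        rng = np.random.default_rng(8)
        probs = rng.dirichlet(np.full(60, 0.1))
        terms = [f"t{i:03d}" for i in range(60)]
        docs = [
            TokenDoc(f"d{i}", [terms[j] for j in rng.choice(60, size=50, p=probs)])
            for i in range(300)
        ]
        bow = build_bow(docs, min_count=1)
        model = tm.fit(bow, tm.LDAConfig(K=2, iterations=150, burn_in=100, thin=5, seed=8))
        true_top = set(np.argsort(-probs)[:10])
        true_terms = {terms[j] for j in true_top}
        best_overlap = max(
            len(set(tm.top_words(model, k, 10)) & true_terms) for k in range(2)
        )
        assert best_overlap >= 9

    def test_topic_recovery(self, fitted):
        model, _, phi_true = fitted
        assert greedy_matched_cosine(model.phi, phi_true) >= 0.80


class TestPerplexity:
    def test_uniform_phi_equals_vocab_size(self, topic_corpus):
        bow, _, _ = topic_corpus
        v = len(bow.vocab)
        model = tm.LDAModel(
            phi=np.full((3, v), 1.0 / v),
            theta=np.full((bow.n_docs, 3), 1.0 / 3),
            assignments=np.zeros(0, dtype=np.int64),
            config=tm.LDAConfig(K=3, iterations=10, burn_in=5),
            vocab_terms=list(bow.vocab.id2term),
        )
        assert tm.perplexity(model, bow) == pytest.approx(v, rel=1e-12)

    def test_structured_beats_word_permuted(self, fitted, topic_corpus):
        """Perplexity on real documents <= on documents with words scrambled
        across the corpus (which destroys the topic structure)."""
        model, bow, _ = fitted
        rng = np.random.default_rng(0)
        arr = bow.matrix.toarray()
        perm = arr.flatten()
        rng.shuffle(perm)
        scrambled = perm.reshape(arr.shape)
        import scipy.sparse as sp

        from cravingminer.corpus_io import BOWCorpus

        perm_bow = BOWCorpus(
            vocab=bow.vocab, matrix=sp.csr_matrix(scrambled), doc_ids=bow.doc_ids
        )
        assert tm.perplexity(model, bow) <= tm.perplexity(model, perm_bow)

    def test_exchangeability(self, fitted, topic_corpus):
        """Relabeling topics leaves perplexity invariant.

        Fold-in is a Monte Carlo estimate whose sampling path depends on
        topic order, so invariance holds statistically rather than to
        machine precision.
        """
        model, bow, _ = fitted
        perm = np.array([2, 0, 4, 1, 3])
        relabeled = tm.LDAModel(
            phi=model.phi[perm],
            theta=model.theta[:, perm],
            assignments=model.assignments,
            config=model.config,
            vocab_terms=model.vocab_terms,
        )
        _, val = tm.split_corpus(bow, 0.1, seed=3)
        assert tm.perplexity(model, val) == pytest.approx(tm.perplexity(relabeled, val), rel=1e-2)


class TestNPMICoherence:
    def test_hand_counting_oracle(self):
        docs = [
            TokenDoc("a", ["xx", "yy", "qq"]),
            TokenDoc("b", ["xx", "yy"]),
            TokenDoc("c", ["xx", "zz"]),
            TokenDoc("d", ["zz", "qq"]),
        ]
        bow = build_bow(docs, min_count=1)
        eps = 1e-12
        # by hand: p(xx)=3/4, p(yy)=1/2, p(xx,yy)=1/2
        expected = math.log((0.5 + eps) / (0.75 * 0.5)) / (-math.log(0.5 + eps))
        assert tm.npmi_coherence(bow, ["xx", "yy"]) == pytest.approx(expected, abs=1e-9)

    def test_independent_words_zero(self):
        # 4-doc grid: xx in {a,b}, yy in {a,c}: joint 1/4 = 1/2 * 1/2 exactly
        docs = [
            TokenDoc("a", ["xx", "yy"]),
            TokenDoc("b", ["xx", "ww"]),
            TokenDoc("c", ["yy", "ww"]),
            TokenDoc("d", ["ww", "qq"]),
        ]
        bow = build_bow(docs, min_count=1)
        assert tm.npmi_coherence(bow, ["xx", "yy"]) == pytest.approx(0.0, abs=1e-9)

    def test_always_cooccurring_approaches_one(self):
        docs = [TokenDoc(f"t{i}", ["xx", "yy"]) for i in range(5)]
        docs += [TokenDoc(f"f{i}", ["ww", "qq"]) for i in range(5)]
        bow = build_bow(docs, min_count=1)
        assert tm.npmi_coherence(bow, ["xx", "yy"], epsilon=1e-15) == pytest.approx(1.0, abs=1e-12)

    def test_absent_word_pairs_skipped(self):
        docs = [TokenDoc("a", ["xx", "yy"]), TokenDoc("b", ["xx", "yy"])]
        bow = build_bow(docs, min_count=1)
        both = tm.npmi_coherence(bow, ["xx", "yy"])
        with_ghost = tm.npmi_coherence(bow, ["xx", "yy", "ghost"])
        assert with_ghost == pytest.approx(both)

    def test_bounds(self, fitted):
        model, bow, _ = fitted
        for k in range(model.config.K):
            c = tm.npmi_coherence(bow, tm.top_words(model, k, 10))
            assert -1.0 <= c <= 1.0


class TestSummarize:
    def test_word_shares_partition_vocabulary(self, fitted):
        model, bow, _ = fitted
        summary = tm.summarize(model, bow, top_n=12)
        assert summary.word_shares.sum() == pytest.approx(100.0, abs=0.01)

    def test_sorted_by_decreasing_coherence(self, fitted):
        model, bow, _ = fitted
        coh = tm.summarize(model, bow, top_n=12).table["coherence"].to_numpy()
        assert (np.diff(coh) <= 1e-12).all()

    def test_twelve_keyword_layout(self, fitted):
        model, bow, _ = fitted
        table = tm.summarize(model, bow, top_n=12).table
        assert all(len(ws) == 12 for ws in table["top_words"])
        assert set(table.columns) >= {"topic", "top_words", "coherence", "word_share_pct"}

    def test_top_words_within_matched_true_topic(self, fitted, topic_corpus):
        """Each fitted topic's top-5 words lie in its matched true topic's top-20."""
        model, bow, phi_true = fitted
        terms = model.vocab_terms
        for k in range(5):
            sims = [
                model.phi[k] @ phi_true[j]
                / (np.linalg.norm(model.phi[k]) * np.linalg.norm(phi_true[j]))
                for j in range(5)
            ]
            j = int(np.argmax(sims))
            true_top20 = {terms[w] for w in np.argsort(-phi_true[j])[:20]}
            assert set(tm.top_words(model, k, 5)) <= true_top20

    def test_relabeling_leaves_coherence_multiset_invariant(self, fitted):
        model, bow, _ = fitted
        perm = np.array([4, 3, 2, 1, 0])
        relabeled = tm.LDAModel(
            phi=model.phi[perm],
            theta=model.theta[:, perm],
            assignments=model.assignments,
            config=model.config,
            vocab_terms=model.vocab_terms,
        )
        a = sorted(tm.summarize(model, bow).table["coherence"])
        b = sorted(tm.summarize(relabeled, bow).table["coherence"])
        assert a == pytest.approx(b)
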