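"""Shared fixtures: small synthetic corpora generated once per session."""

import numpy as np
import pytest

from cravingminer import synthetic_data as sd


@pytest.fixture(scope="session")
def small_corpus():
    """500-author corpus with default study conditions and its ground truth."""
    return sd.generate_corpus(sd.GeneratorConfig(seed=11, n_authors=500))


@pytest.fixture(scope="session")
def big_corpus():
    """5000-author corpus at the recovery-test scale."""
    return sd.generate_corpus(sd.GeneratorConfig(seed=0, n_authors=5000))


@pytest.fixture(scope="session")
def topic_corpus():
    """LDA-generated corpus (K=5, V=200, D=1000, 80 tokens/doc) with truth."""
    return sd.generate_topic_corpus(K=5, V=200, D=1000, doc_len=80, alpha=0.3, beta=0.05, seed=0)


def greedy_matched_cosine(phi_fit: np.ndarray, phi_true: np.ndarray) -> float:
    """Mean cosine between fitted and true topic-word rows under greedy 1:1 matching."""
    k = phi_true.shape[0]
    sims = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            sims[i, j] = phi_fit[i] @ phi_true[j] / (
                np.linalg.norm(phi_fit[i]) * np.linalg.norm(phi_true[j])
            )
    used_f: set = set()
    used_t: set = set()
    vals = []
    for _ in range(k):
        best = max(
            ((i, j) for i in range(k) if i not in used_f for j in range(k) if j not in used_t),
            key=lambda ij: sims[ij],
        )
        used_f.add(best[0])
        used_t.add(best[1])
        vals.append(sims[best])
    return float(np.mean(vals))
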