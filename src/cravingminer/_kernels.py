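"""Numba-compiled inner loops: skip-gram negative sampling and collapsed Gibbs.

Both kernels use an internal xorshift64* generator seeded explicitly so that
training and sampling are bit-reproducible for a given seed, independent of
global NumPy RNG state and thread count (everything here is single-threaded).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_U13 = np.uint64(13)
_U7 = np.uint64(7)
_U17 = np.uint64(17)
_U11 = np.uint64(11)
_MULT = np.uint64(2685821657736338717)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _rng_u64(state):
    x = state[0]
    x ^= x << _U13
    x ^= x >> _U7
    x ^= x << _U17
    state[0] = x
    return x * _MULT


@njit(cache=True, inline="always")
def _rng_uniform(state):
    return float(_rng_u64(state) >> _U11) * _INV53


@njit(cache=True, inline="always")
def _rng_below(state, n):
    return int(_rng_u64(state) % np.uint64(n))


@njit(cache=True)
def _seed_state(seed):
    state = np.empty(1, dtype=np.uint64)
    s = np.uint64(seed) * np.uint64(2654435761) + np.uint64(0x9E3779B97F4A7C15)
    if s == np.uint64(0):
        s = np.uint64(0x9E3779B97F4A7C15)
    state[0] = s
    # warm up past the low-entropy start
    for _ in range(8):
        _rng_u64(state)
    return state


@njit(cache=True, inline="always")
def _sigmoid(x):
    if x > 8.0:
        return 1.0
    if x < -8.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


@njit(cache=True)
def sgns_train(words, offsets, window, n_neg, lr0, epochs, w_in, w_out, neg_table, seed):
    """Train skip-gram with negative sampling in place on w_in / w_out.

    words: int32 token ids concatenated over documents; offsets: int64
    document boundaries (len n_docs+1); neg_table: int32 unigram^0.75
    sampling table.  Learning rate decays linearly over all processed
    centers down to lr0 * 1e-4.
    """
    state = _seed_state(seed)
    dim = w_in.shape[1]
    n_docs = offsets.shape[0] - 1
    total = float(words.shape[0] * epochs)
    table_size = neg_table.shape[0]
    grad = np.empty(dim, dtype=np.float64)
    processed = 0
    min_lr = lr0 * 1e-4
    for _ep in range(epochs):
        for d in range(n_docs):
            start = offsets[d]
            end = offsets[d + 1]
            for i in range(start, end):
                lr = lr0 * (1.0 - processed / total)
                if lr < min_lr:
                    lr = min_lr
                processed += 1
                center = words[i]
                lo = i - window
                if lo < start:
                    lo = start
                hi = i + window + 1
                if hi > end:
                    hi = end
                for j in range(lo, hi):
                    if j == i:
                        continue
                    for m in range(dim):
                        grad[m] = 0.0
                    # one positive target plus n_neg sampled negatives
                    for s in range(n_neg + 1):
                        if s == 0:
                            target = words[j]
                            label = 1.0
                        else:
                            target = neg_table[_rng_below(state, table_size)]
                            if target == words[j]:
                                continue
                            label = 0.0
                        f = 0.0
                        for m in range(dim):
                            f += w_in[center, m] * w_out[target, m]
                        g = (label - _sigmoid(f)) * lr
                        for m in range(dim):
                            grad[m] += g * w_out[target, m]
                            w_out[target, m] += g * w_in[center, m]
                    for m in range(dim):
                        w_in[center, m] += grad[m]


@njit(cache=True)
def lda_gibbs(words, docs, n_docs, n_terms, n_topics, alpha, beta, iterations, burn_in, thin, seed):
    """Collapsed Gibbs sampler for LDA.

    Returns (z, phi, theta, nkw, ndk): final assignments, post-burn-in
    averaged smoothed estimates, and the final count matrices (for
    conservation checks).  The conditional is the standard
    p(z=k) ∝ (n_dk + α)(n_kw + β)/(n_k + Vβ).
    """
    state = _seed_state(seed)
    n = words.shape[0]
    z = np.empty(n, dtype=np.int64)
    ndk = np.zeros((n_docs, n_topics), dtype=np.int64)
    nkw = np.zeros((n_topics, n_terms), dtype=np.int64)
    nk = np.zeros(n_topics, dtype=np.int64)
    nd = np.zeros(n_docs, dtype=np.int64)
    for i in range(n):
        k = _rng_below(state, n_topics)
        z[i] = k
        ndk[docs[i], k] += 1
        nkw[k, words[i]] += 1
        nk[k] += 1
        nd[docs[i]] += 1

    phi_acc = np.zeros((n_topics, n_terms), dtype=np.float64)
    theta_acc = np.zeros((n_docs, n_topics), dtype=np.float64)
    n_samples = 0
    p = np.empty(n_topics, dtype=np.float64)
    vbeta = n_terms * beta
    for it in range(iterations):
        for i in range(n):
            w = words[i]
            d = docs[i]
            k = z[i]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            tot = 0.0
            for kk in range(n_topics):
                p[kk] = (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + vbeta)
                tot += p[kk]
            u = _rng_uniform(state) * tot
            cum = 0.0
            k = n_topics - 1
            for kk in range(n_topics):
                cum += p[kk]
                if u < cum:
                    k = kk
                    break
            z[i] = k
            ndk[d, k] += 1
            nkw[k, w] += 1
            nk[k] += 1
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_samples += 1
            for kk in range(n_topics):
                denom = nk[kk] + vbeta
                for w in range(n_terms):
                    phi_acc[kk, w] += (nkw[kk, w] + beta) / denom
            for d in range(n_docs):
                denom = nd[d] + n_topics * alpha
                for kk in range(n_topics):
                    theta_acc[d, kk] += (ndk[d, kk] + alpha) / denom
    if n_samples == 0:
        n_samples = 1
        for kk in range(n_topics):
            denom = nk[kk] + vbeta
            for w in range(n_terms):
                phi_acc[kk, w] = (nkw[kk, w] + beta) / denom
        for d in range(n_docs):
            denom = nd[d] + n_topics * alpha
            for kk in range(n_topics):
                theta_acc[d, kk] = (ndk[d, kk] + alpha) / denom
    return z, phi_acc / n_samples, theta_acc / n_samples, nkw, ndk


@njit(cache=True)
def lda_foldin(words, docs, n_docs, phi, alpha, iterations, burn_in, seed):
    """Fold-in sampling for held-out documents with the topic-word matrix fixed.

    Returns the averaged smoothed document-topic estimate theta'.
    """
    state = _seed_state(seed)
    n = words.shape[0]
    n_topics = phi.shape[0]
    z = np.empty(n, dtype=np.int64)
    ndk = np.zeros((n_docs, n_topics), dtype=np.int64)
    nd = np.zeros(n_docs, dtype=np.int64)
    for i in range(n):
        k = _rng_below(state, n_topics)
        z[i] = k
        ndk[docs[i], k] += 1
        nd[docs[i]] += 1
    theta_acc = np.zeros((n_docs, n_topics), dtype=np.float64)
    n_samples = 0
    p = np.empty(n_topics, dtype=np.float64)
    for it in range(iterations):
        for i in range(n):
            w = words[i]
            d = docs[i]
            k = z[i]
            ndk[d, k] -= 1
            tot = 0.0
            for kk in range(n_topics):
                p[kk] = (ndk[d, kk] + alpha) * phi[kk, w]
                tot += p[kk]
            u = _rng_uniform(state) * tot
            cum = 0.0
            k = n_topics - 1
            for kk in range(n_topics):
                cum += p[kk]
                if u < cum:
                    k = kk
                    break
            z[i] = k
            ndk[d, k] += 1
        if it >= burn_in:
            n_samples += 1
            for d in range(n_docs):
                denom = nd[d] + n_topics * alpha
                for kk in range(n_topics):
                    theta_acc[d, kk] += (ndk[d, kk] + alpha) / denom
    if n_samples == 0:
        n_samples = 1
        for d in range(n_docs):
            denom = nd[d] + n_topics * alpha
            for kk in range(n_topics):
                theta_acc[d, kk] = (ndk[d, kk] + alpha) / denom
    return theta_acc / n_samples
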