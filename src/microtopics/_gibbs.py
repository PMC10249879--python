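"""Numba kernels for collapsed Gibbs sampling.

One legacy numpy random stream is seeded inside the kernel, so an identical
(corpus, K, hyperparameters, n_iter, seed) tuple yields bit-identical
assignments.  Sampling order is document order then token order.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def _joint_log_likelihood(ndk, nkw, nk, nd, alpha, beta):
    """Collapsed joint log P(w, z | alpha, beta): two Dirichlet-multinomial
    blocks, one over document-topic counts, one over topic-word counts."""
    D, K = ndk.shape
    V = nkw.shape[1]
    alpha_sum = 0.0
    for k in range(K):
        alpha_sum += alpha[k]
    ll = 0.0
    for d in range(D):
        ll += math.lgamma(alpha_sum) - math.lgamma(alpha_sum + nd[d])
        for k in range(K):
            if ndk[d, k] > 0:
                ll += math.lgamma(alpha[k] + ndk[d, k]) - math.lgamma(alpha[k])
    vbeta = V * beta
    for k in range(K):
        ll += math.lgamma(vbeta) - math.lgamma(vbeta + nk[k])
        for w in range(V):
            if nkw[k, w] > 0:
                ll += math.lgamma(beta + nkw[k, w]) - math.lgamma(beta)
    return ll


@njit(cache=False)
def run_gibbs(doc_ids, word_ids, K, V, D, alpha, beta, n_iter, record_at, seed):
    """Collapsed Gibbs sampler.

    Returns (z, ndk, nkw, nk, ll_per_word) where ll_per_word[i] is the
    joint log-likelihood per token after sweep record_at[i].
    """
    np.random.seed(seed)
    n_tokens = doc_ids.shape[0]
    z = np.empty(n_tokens, dtype=np.int32)
    ndk = np.zeros((D, K), dtype=np.int64)
    nkw = np.zeros((K, V), dtype=np.int64)
    nk = np.zeros(K, dtype=np.int64)
    nd = np.zeros(D, dtype=np.int64)
    for i in range(n_tokens):
        k = np.random.randint(0, K)
        z[i] = k
        ndk[doc_ids[i], k] += 1
        nkw[k, word_ids[i]] += 1
        nk[k] += 1
        nd[doc_ids[i]] += 1

    vbeta = V * beta
    p = np.empty(K, dtype=np.float64)
    ll_out = np.empty(record_at.shape[0], dtype=np.float64)
    rec = 0
    for sweep in range(n_iter):
        for i in range(n_tokens):
            d = doc_ids[i]
            w = word_ids[i]
            k = z[i]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            total = 0.0
            for kk in range(K):
                pk = (ndk[d, kk] + alpha[kk]) * (nkw[kk, w] + beta) / (nk[kk] + vbeta)
                p[kk] = pk
                total += pk
            u = np.random.random() * total
            acc = 0.0
            knew = K - 1
            for kk in range(K):
                acc += p[kk]
                if u < acc:
                    knew = kk
                    break
            z[i] = knew
            ndk[d, knew] += 1
            nkw[knew, w] += 1
            nk[knew] += 1
        if rec < record_at.shape[0] and record_at[rec] == sweep:
            ll_out[rec] = _joint_log_likelihood(ndk, nkw, nk, nd, alpha, beta) / n_tokens
            rec += 1
    return z, ndk, nkw, nk, ll_out


@njit(cache=False)
def run_fold_in(doc_ids, word_ids, K, D, alpha, phi, n_iter, seed):
    """Gibbs fold-in for held-out documents with frozen topic-word
    probabilities: p(z=k) ~ (n_dk + alpha_k) * phi[k, w]."""
    np.random.seed(seed)
    n_tokens = doc_ids.shape[0]
    z = np.empty(n_tokens, dtype=np.int32)
    ndk = np.zeros((D, K), dtype=np.int64)
    for i in range(n_tokens):
        k = np.random.randint(0, K)
        z[i] = k
        ndk[doc_ids[i], k] += 1
    p = np.empty(K, dtype=np.float64)
    for sweep in range(n_iter):
        for i in range(n_tokens):
            d = doc_ids[i]
            w = word_ids[i]
            k = z[i]
            ndk[d, k] -= 1
            total = 0.0
            for kk in range(K):
                pk = (ndk[d, kk] + alpha[kk]) * phi[kk, w]
                p[kk] = pk
                total += pk
            u = np.random.random() * total
            acc = 0.0
            knew = K - 1
            for kk in range(K):
                acc += p[kk]
                if u < acc:
                    knew = kk
                    break
            z[i] = knew
            ndk[d, knew] += 1
    return ndk
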