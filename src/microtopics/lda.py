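"""Latent Dirichlet Allocation for microbiome count tables.

Samples play the role of documents, taxa the role of words, and topics are
sub-communities: probability distributions over taxa that mix to produce
each sample's composition.  The model is fitted by collapsed Gibbs
sampling; each token's topic is resampled with probability proportional to

    (n_dk + alpha_k) * (n_kw + beta) / (n_k + V * beta)

with the token itself excluded from the counts.  Point estimates of the
topic-taxon matrix (phi) and sample-topic matrix (theta) come from the
final Gibbs state with Dirichlet smoothing.  Defaults follow the common
Gibbs-LDA toolchain convention: symmetric alpha summing to 5, beta = 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io import CountMatrix
from ._gibbs import run_gibbs, run_fold_in

DEFAULT_ALPHA_SUM = 5.0
DEFAULT_BETA = 0.01


@dataclass
class GibbsState:
    """Token-level assignments and their count-table marginals."""

    doc_ids: np.ndarray
    word_ids: np.ndarray
    z: np.ndarray
    doc_topic: np.ndarray   # D x K
    topic_word: np.ndarray  # K x V
    topic_totals: np.ndarray  # K
    doc_totals: np.ndarray    # D

    def check_consistency(self) -> None:
        """Verify the count tables are exact marginals of the assignments."""
        K = self.doc_topic.shape[1]
        V = self.topic_word.shape[1]
        ndk = np.zeros_like(self.doc_topic)
        nkw = np.zeros_like(self.topic_word)
        np.add.at(ndk, (self.doc_ids, self.z), 1)
        np.add.at(nkw, (self.z, self.word_ids), 1)
        if not (ndk == self.doc_topic).all() or not (nkw == self.topic_word).all():
            raise AssertionError("count tables are not marginals of assignments")
        if not (self.topic_word.sum(axis=1) == self.topic_totals).all():
            raise AssertionError("topic totals inconsistent")


@dataclass
class LdaModel:
    """A fitted LDA model.

    Attributes
    ----------
    K : number of topics
    alpha : per-topic Dirichlet concentration, length K
    beta : symmetric taxon-side concentration
    phi : (K, V) topic-taxon probabilities, rows sum to 1
    theta : (D, K) sample-topic proportions, rows sum to 1
    ll_trace : (sweep index, joint log-likelihood per token) pairs
    state : final Gibbs state (None for analytically built models)
    """

    K: int
    alpha: np.ndarray
    beta: float
    phi: np.ndarray
    theta: np.ndarray
    vocab: list[str]
    sample_ids: list[str]
    seed: int | None = None
    n_iter: int = 0
    ll_trace: np.ndarray | None = None  # shape (n_recorded, 2)
    state: GibbsState | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("phi rows must sum to 1")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("theta rows must sum to 1")
        if (self.phi < 0).any() or (self.theta < 0).any():
            raise ValueError("probabilities must be non-negative")

    @property
    def n_taxa(self) -> int:
        return self.phi.shape[1]


def _expand_tokens(matrix: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    counts = matrix.data.to_numpy()
    docs, words = np.nonzero(counts)
    reps = counts[docs, words]
    return (
        np.repeat(docs, reps).astype(np.int32),
        np.repeat(words, reps).astype(np.int32),
    )


def _resolve_alpha(alpha, K: int) -> np.ndarray:
    if alpha is None:
        alpha = np.full(K, DEFAULT_ALPHA_SUM / K)
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.ndim == 0:
        alpha = np.full(K, float(alpha))
    if alpha.shape != (K,) or (alpha <= 0).any():
        raise ValueError("alpha must be K positive concentrations")
    return alpha


def _trace_sweeps(n_iter: int) -> np.ndarray:
    """Sweeps at which log-likelihood is recorded: every sweep up to 1000,
    every 10th afterwards (bounded memory at long runs)."""
    if n_iter <= 1000:
        return np.arange(n_iter, dtype=np.int64)
    tail = np.arange(1009, n_iter, 10, dtype=np.int64)
    return np.concatenate([np.arange(1000, dtype=np.int64), tail])


def fit_lda(
    matrix: CountMatrix,
    K: int,
    alpha: np.ndarray | float | None = None,
    beta: float = DEFAULT_BETA,
    n_iter: int = 10_000,
    seed: int = 0,
) -> LdaModel:
    """Fit LDA to a count matrix by collapsed Gibbs sampling.

    ``n_iter`` sweeps over every token; the default (10,000) is generous
    enough for the per-token log-likelihood to stabilize on amplicon-scale
    tables.  Identical inputs and seed give a bit-identical model.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be positive")
    alpha = _resolve_alpha(alpha, K)
    totals = matrix.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total count: {list(zero.index)}")
    n_tokens = int(totals.sum())
    if K > n_tokens:
        raise ValueError(f"K={K} exceeds total token count {n_tokens}")

    doc_ids, word_ids = _expand_tokens(matrix)
    D, V = matrix.n_samples, matrix.n_taxa
    record_at = _trace_sweeps(n_iter)
    z, ndk, nkw, nk, ll = run_gibbs(
        doc_ids, word_ids, K, V, D, alpha, float(beta), n_iter, record_at,
        np.uint32(seed),
    )
    nd = ndk.sum(axis=1)
    phi = (nkw + beta) / (nk[:, None] + V * beta)
    theta = (ndk + alpha) / (nd[:, None] + alpha.sum())
    state = GibbsState(
        doc_ids=doc_ids, word_ids=word_ids, z=z,
        doc_topic=ndk, topic_word=nkw, topic_totals=nk, doc_totals=nd,
    )
    trace = np.column_stack([record_at.astype(np.float64), ll])
    return LdaModel(
        K=K, alpha=alpha, beta=float(beta), phi=phi, theta=theta,
        vocab=matrix.taxon_ids, sample_ids=matrix.sample_ids,
        seed=seed, n_iter=n_iter, ll_trace=trace, state=state,
    )


def log_likelihood_per_word(
    state: GibbsState, alpha: np.ndarray, beta: float
) -> float:
    """Collapsed joint log P(w, z | alpha, beta) divided by token count.

    The closed form is a product of Dirichlet-multinomial terms, one per
    document over topics and one per topic over taxa.
    """
    n_tokens = state.doc_ids.shape[0]
    if n_tokens == 0:
        raise ValueError("empty corpus")
    alpha = np.asarray(alpha, dtype=np.float64)
    ndk = state.doc_topic
    nkw = state.topic_word
    nk = state.topic_totals
    nd = state.doc_totals
    V = nkw.shape[1]
    a_sum = alpha.sum()
    ll = (
        (gammaln(a_sum) - gammaln(a_sum + nd)).sum()
        + (gammaln(alpha[None, :] + ndk) - gammaln(alpha[None, :])).sum()
        + (gammaln(V * beta) - gammaln(V * beta + nk)).sum()
        + (gammaln(beta + nkw) - gammaln(beta)).sum()
    )
    return float(ll) / n_tokens


def infer_heldout_theta(
    model: LdaModel,
    heldout: CountMatrix,
    n_iter: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Infer topic proportions for unseen samples by Gibbs fold-in.

    The topic-taxon matrix is frozen; only document-side assignments are
    resampled.  Taxa outside the model vocabulary are dropped with a
    warning; a sample with no in-vocabulary tokens gets a uniform theta.
    """
    vocab_index = {w: i for i, w in enumerate(model.vocab)}
    oov = [t for t in heldout.taxon_ids if t not in vocab_index]
    if oov:
        warnings.warn(
            f"dropping {len(oov)} out-of-vocabulary taxa from held-out data",
            stacklevel=2,
        )
    in_vocab = [t for t in heldout.taxon_ids if t in vocab_index]
    counts = heldout.data[in_vocab].to_numpy(dtype=np.int64)
    D = counts.shape[0]
    K = model.K

    docs, cols = np.nonzero(counts)
    reps = counts[docs, cols]
    word_ids = np.repeat(
        np.array([vocab_index[t] for t in in_vocab], dtype=np.int32)[cols], reps
    ).astype(np.int32)
    doc_ids = np.repeat(docs, reps).astype(np.int32)

    if doc_ids.shape[0] == 0:
        ndk = np.zeros((D, K), dtype=np.int64)
    else:
        ndk = run_fold_in(
            doc_ids, word_ids, K, D, model.alpha, model.phi, n_iter,
            np.uint32(seed),
        )
    nd = ndk.sum(axis=1)
    empty = nd == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} held-out samples have no in-vocabulary "
            "tokens; returning uniform proportions",
            stacklevel=2,
        )
    theta = (ndk + model.alpha) / (nd[:, None] + model.alpha.sum())
    theta[empty] = 1.0 / K
    return theta
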