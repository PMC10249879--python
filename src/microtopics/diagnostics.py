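"""Model-selection metrics and cross-run topic consistency.

The number of topics K is the main tuning knob of LDA.  Too few topics miss
structure; too many produce redundant, poorly conditioned factorizations.
This module computes the standard battery used to choose K — held-out
perplexity, pairwise cosine similarity between topics, UMass coherence, and
top-word exclusivity — under repeated k-fold cross-validation, plus the
effective number of words per topic and optimal topic matching between
independent runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.model_selection import KFold

from .io import CountMatrix
from .lda import LdaModel, fit_lda, infer_heldout_theta


def perplexity(
    model: LdaModel,
    heldout: CountMatrix,
    fold_in_iters: int = 200,
    seed: int = 0,
) -> float:
    """Held-out perplexity: exp of minus the per-token predictive
    log-likelihood under fold-in topic proportions.

    Lower is better; a model uniform over V taxa scores exactly V.
    """
    vocab = set(model.vocab)
    in_vocab = [t for t in heldout.taxon_ids if t in vocab]
    counts = heldout.data[in_vocab].to_numpy()
    n_tokens = counts.sum()
    if n_tokens == 0:
        raise ValueError("no in-vocabulary tokens in held-out data")
    theta = infer_heldout_theta(model, heldout, n_iter=fold_in_iters, seed=seed)
    # P(w | d) = sum_k theta_dk phi_kw, restricted to observed columns
    col_idx = [model.vocab.index(t) for t in in_vocab]
    probs = theta @ model.phi[:, col_idx]
    ll = float((counts * np.log(probs, where=counts > 0,
                                out=np.zeros_like(probs))).sum())
    return math.exp(-ll / n_tokens)


@dataclass
class CosineSummary:
    mean: float          # nan when K == 1 (undefined)
    matrix: np.ndarray   # K x K, empty for K == 1
    defined: bool


def _cosine_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = a / np.linalg.norm(a, axis=1, keepdims=True)
    nb = b / np.linalg.norm(b, axis=1, keepdims=True)
    return na @ nb.T


def pairwise_cosine(model: LdaModel) -> CosineSummary:
    """Cosine similarity between all unordered pairs of topic-taxa vectors.

    High mean similarity signals redundant topics (K too large).
    """
    if model.K < 2:
        return CosineSummary(mean=float("nan"), matrix=np.empty((0, 0)), defined=False)
    m = _cosine_matrix(model.phi, model.phi)
    iu = np.triu_indices(model.K, k=1)
    return CosineSummary(mean=float(m[iu].mean()), matrix=m, defined=True)


def _top_taxa(model: LdaModel, k: int, top_m: int) -> list[int]:
    """Indices of topic k's top-M taxa by probability; ties broken by
    taxon label order."""
    order = sorted(range(model.n_taxa),
                   key=lambda w: (-model.phi[k, w], model.vocab[w]))
    return order[:top_m]


def coherence(model: LdaModel, corpus: CountMatrix, top_m: int = 10) -> np.ndarray:
    """UMass coherence per topic: smoothed log co-document frequency of the
    topic's top-M taxa, summed over ordered pairs.

    For top taxa v_1..v_M (descending probability) the score is
    sum_{m=2..M} sum_{l<m} log[(D(v_m, v_l) + 1) / D(v_l)] where D counts
    samples in which a taxon occurs (count > 0).  Closer to zero means the
    topic's defining taxa genuinely co-occur in samples.
    """
    if top_m < 2:
        raise ValueError("top_m must be >= 2")
    counts = corpus.data.to_numpy() > 0
    col = {t: i for i, t in enumerate(corpus.taxon_ids)}
    scores = np.zeros(model.K)
    for k in range(model.K):
        top = [w for w in _top_taxa(model, k, top_m) if model.vocab[w] in col]
        s = 0.0
        for m in range(1, len(top)):
            vm = counts[:, col[model.vocab[top[m]]]]
            for l in range(m):
                vl = counts[:, col[model.vocab[top[l]]]]
                d_l = int(vl.sum())
                if d_l == 0:
                    raise ValueError(
                        f"taxon {model.vocab[top[l]]!r} absent from every sample"
                    )
                d_ml = int((vm & vl).sum())
                s += math.log((d_ml + 1) / d_l)
        scores[k] = s
    return scores


def exclusivity(model: LdaModel, top_m: int = 10) -> np.ndarray:
    """Per-topic mean probability share of its top-M taxa.

    A taxon's share is phi_kw / sum_k' phi_k'w: 1 when the taxon has
    support in one topic only, 1/K when spread evenly.
    """
    if model.K < 2:
        raise ValueError("exclusivity needs K >= 2")
    col_sums = model.phi.sum(axis=0)
    out = np.zeros(model.K)
    for k in range(model.K):
        top = _top_taxa(model, k, top_m)
        out[k] = float(np.mean([model.phi[k, w] / col_sums[w] for w in top]))
    return out


def effective_number_of_words(model: LdaModel) -> np.ndarray:
    """Inverse Simpson concentration of each topic: 1 / sum_w phi_kw^2.

    Ranges from 1 (point mass) to V (uniform); counts how many taxa a
    topic is effectively spread across.
    """
    return 1.0 / (model.phi ** 2).sum(axis=1)


def important_taxa(model: LdaModel) -> list[list[str]]:
    """Per topic, the taxa whose probability rank is within ceil(ENW):
    the taxa that contribute importantly to the topic."""
    enw = effective_number_of_words(model)
    out = []
    for k in range(model.K):
        cutoff = math.ceil(enw[k])
        out.append([model.vocab[w] for w in _top_taxa(model, k, cutoff)])
    return out


@dataclass
class SelectionReport:
    """Per-K metric summary over folds x repeats."""

    summary: pd.DataFrame          # indexed by K
    per_topic_enw: dict[int, np.ndarray]
    folds: int
    repeats: int


def cross_validate_k(
    matrix: CountMatrix,
    k_grid: list[int],
    folds: int = 5,
    repeats: int = 5,
    iters: int = 500,
    fold_in_iters: int = 200,
    seed: int = 0,
    alpha=None,
    beta: float = 0.01,
) -> SelectionReport:
    """Repeated k-fold cross-validation over a grid of topic counts.

    For each K and repeat, samples are split into folds; perplexity is
    measured on each held-out fold after fitting on the rest.  The
    similarity/coherence/exclusivity/ENW metrics are computed on a
    full-data fit per repeat.  All sub-seeds derive deterministically from
    the master seed.
    """
    if folds > matrix.n_samples:
        raise ValueError(f"folds={folds} exceeds sample count {matrix.n_samples}")
    rng = np.random.default_rng(seed)
    rows = []
    per_topic_enw: dict[int, np.ndarray] = {}
    for K in k_grid:
        ppl_vals, cos_vals, coh_vals, exc_vals = [], [], [], []
        enw_acc = np.zeros(K)
        for _ in range(repeats):
            kf = KFold(n_splits=folds, shuffle=True,
                       random_state=int(rng.integers(2**31)))
            for train_idx, test_idx in kf.split(np.arange(matrix.n_samples)):
                train = CountMatrix(matrix.data.iloc[train_idx])
                test = CountMatrix(matrix.data.iloc[test_idx])
                m = fit_lda(train, K, alpha=alpha, beta=beta, n_iter=iters,
                            seed=int(rng.integers(2**31)))
                ppl_vals.append(
                    perplexity(m, test, fold_in_iters=fold_in_iters,
                               seed=int(rng.integers(2**31)))
                )
            full = fit_lda(matrix, K, alpha=alpha, beta=beta, n_iter=iters,
                           seed=int(rng.integers(2**31)))
            cs = pairwise_cosine(full)
            cos_vals.append(cs.mean if cs.defined else float("nan"))
            coh_vals.append(float(coherence(full, matrix).mean()))
            exc_vals.append(float(exclusivity(full).mean()) if K >= 2
                            else float("nan"))
            enw_acc += effective_number_of_words(full)
        per_topic_enw[K] = enw_acc / repeats
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-nan means at K=1
            rows.append({
                "K": K,
                "perplexity_mean": float(np.mean(ppl_vals)),
                "perplexity_sd": float(np.std(ppl_vals, ddof=1))
                if len(ppl_vals) > 1 else 0.0,
                "cosine_mean": float(np.nanmean(cos_vals))
                if not all(np.isnan(cos_vals)) else float("nan"),
                "coherence_mean": float(np.mean(coh_vals)),
                "exclusivity_mean": float(np.nanmean(exc_vals))
                if not all(np.isnan(exc_vals)) else float("nan"),
                "enw_mean": float(per_topic_enw[K].mean()),
            })
    return SelectionReport(
        summary=pd.DataFrame(rows).set_index("K"),
        per_topic_enw=per_topic_enw,
        folds=folds,
        repeats=repeats,
    )


@dataclass
class TopicMatch:
    """Optimal one-to-one topic correspondence between two runs."""

    run_a: int
    run_b: int
    assignment: np.ndarray    # assignment[i] = topic of run_b matched to i
    similarities: np.ndarray  # cosine of matched pairs

    @property
    def total(self) -> float:
        return float(self.similarities.sum())


def match_topics_across_runs(models: list[LdaModel]) -> list[TopicMatch]:
    """Match topics between every pair of runs by maximizing total cosine
    similarity (optimal bipartite assignment).

    Consistency across independently seeded runs indicates the topics are
    real structure rather than sampler noise.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    K = models[0].K
    vocab = models[0].vocab
    for m in models[1:]:
        if m.K != K:
            raise ValueError(f"K mismatch: {m.K} != {K}")
        if m.vocab != vocab:
            raise ValueError("vocabulary mismatch between runs")
    out = []
    for a in range(len(models)):
        for b in range(a + 1, len(models)):
            sim = _cosine_matrix(models[a].phi, models[b].phi)
            rows, cols = linear_sum_assignment(-sim)
            out.append(TopicMatch(
                run_a=a, run_b=b,
                assignment=cols,
                similarities=sim[rows, cols],
            ))
    return out
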