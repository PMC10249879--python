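"""Topic-condition association strength, plot coordinates, relative
amplification, and topic/taxon-trait correlation tests.

For a two-level condition (say half-water vs full-water) each topic i gets
a summed contribution f_{i,t} = sum of its theta entries over the samples
at level t, a per-level share x_{i,t} = f_{i,t} / sum over topics of
f_{.,t}, and a per-topic weighting w_{i,t} = x_{i,t} / (x_{i,t1} + x_{i,t2}).
Because theta rows sum to one, x_{i,t} equals the mean topic abundance at
level t, so a 4:1 abundance ratio corresponds exactly to w = 0.8 and a 2:1
ratio to w = 2/3.  The plot coordinate maps w onto [-1, 1]:

    c = (1 - 2*w_t1) / w_t1   if w_t1 > w_t2   (level t1 side, negative)
    c = (2*w_t2 - 1) / w_t2   if w_t2 > w_t1   (level t2 side, positive)

so |c| = 0.75 at the strong (4:1) boundary and |c| = 0.5 at the moderate
(2:1) boundary.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix
from .lda import LdaModel

STRONG_RATIO = 4.0
MODERATE_RATIO = 2.0


def _theta_frame(theta, labels) -> tuple[pd.DataFrame, pd.Series]:
    theta = pd.DataFrame(np.asarray(theta, dtype=float))
    labels = pd.Series(labels).reset_index(drop=True)
    if len(labels) != len(theta):
        raise ValueError("labels and theta must align sample-wise")
    return theta, labels


def plot_coordinate(w1: float, w2: float) -> float:
    """Map a per-topic two-level weighting (w1 + w2 = 1) to [-1, 1]."""
    if not np.isclose(w1 + w2, 1.0):
        raise ValueError("w1 + w2 must equal 1")
    if np.isclose(w1, w2):
        return 0.0
    if w1 > w2:
        return (1.0 - 2.0 * w1) / w1
    return (2.0 * w2 - 1.0) / w2


def topic_weighting(theta, labels, level_order: list[str] | None = None) -> pd.DataFrame:
    """Topic weighting for a two-level condition.

    Returns one row per topic with f, x, w per level, the plot coordinate
    (negative side = first level), and the association strength class.
    """
    theta, labels = _theta_frame(theta, labels)
    levels = level_order or list(dict.fromkeys(labels))
    if len(levels) != 2:
        raise ValueError(f"topic_weighting needs exactly 2 levels, got {levels}")
    t1, t2 = levels
    rows = []
    f = {t: theta[labels.to_numpy() == t].sum(axis=0) for t in (t1, t2)}
    for t in (t1, t2):
        if f[t].sum() == 0:
            raise ValueError(f"level {t!r} has all-zero topic mass")
    x = {t: f[t] / f[t].sum() for t in (t1, t2)}
    mean = {t: theta[labels.to_numpy() == t].mean(axis=0) for t in (t1, t2)}
    for i in range(theta.shape[1]):
        w1 = x[t1][i] / (x[t1][i] + x[t2][i])
        w2 = 1.0 - w1
        focal = t1 if mean[t1][i] >= mean[t2][i] else t2
        strength = _strength_from_ratio(
            _min_ratio(mean[focal][i], [mean[t2 if focal == t1 else t1][i]])
        )
        rows.append({
            "topic": i, "condition_level_1": t1, "condition_level_2": t2,
            f"mean_{t1}": mean[t1][i], f"mean_{t2}": mean[t2][i],
            f"f_{t1}": f[t1][i], f"f_{t2}": f[t2][i],
            f"x_{t1}": x[t1][i], f"x_{t2}": x[t2][i],
            f"w_{t1}": w1, f"w_{t2}": w2,
            "coordinate": plot_coordinate(w1, w2),
            "associated_level": focal if strength != "none" else "",
            "strength": strength,
        })
    return pd.DataFrame(rows)


def _min_ratio(focal_mean: float, alt_means: list[float]) -> float:
    """Smallest focal/alternative abundance ratio over alternative levels.

    An alternative with zero mean against a positive focal mean gives an
    infinite ratio (degenerate but valid)."""
    ratios = []
    for alt in alt_means:
        if alt == 0:
            ratios.append(np.inf if focal_mean > 0 else np.nan)
        else:
            ratios.append(focal_mean / alt)
    arr = np.asarray(ratios, dtype=float)
    if np.isnan(arr).all():
        return np.nan
    return float(np.nanmin(arr))


def _strength_from_ratio(ratio: float) -> str:
    if np.isnan(ratio):
        return "none"
    if ratio >= STRONG_RATIO:
        return "strong"
    if ratio >= MODERATE_RATIO:
        return "moderate"
    return "none"


def classify_association(theta, labels, focal_level: str) -> pd.DataFrame:
    """Association strength of each topic with a focal condition level.

    A topic is strongly associated when its mean abundance under the focal
    level is at least four times the mean under EVERY alternative level
    (min-over-alternatives rule), moderately associated at a factor of at
    least two but under four, otherwise unassociated.
    """
    theta, labels = _theta_frame(theta, labels)
    levels = list(dict.fromkeys(labels))
    if focal_level not in levels:
        raise ValueError(f"focal level {focal_level!r} not among levels {levels}")
    for t in levels:
        if (labels == t).sum() == 0:
            raise ValueError(f"empty level {t!r}")
    means = {t: theta[labels.to_numpy() == t].mean(axis=0) for t in levels}
    alts = [t for t in levels if t != focal_level]
    rows = []
    for i in range(theta.shape[1]):
        ratio = _min_ratio(means[focal_level][i], [means[t][i] for t in alts])
        rows.append({
            "topic": i,
            "focal_level": focal_level,
            "mean_focal": means[focal_level][i],
            "min_ratio": ratio,
            "strength": _strength_from_ratio(ratio),
            "degenerate": bool(np.isinf(ratio) or np.isnan(ratio)),
        })
    return pd.DataFrame(rows)


def relative_amplification(model: LdaModel, corpus: CountMatrix) -> pd.DataFrame:
    """Lift of each taxon within each topic, normalized per topic.

    Raw lift is P(taxon | topic) divided by the taxon's overall frequency
    in the corpus; within each topic the lifts are rescaled to sum to one.
    The most amplified taxa are those over-represented in the topic
    relative to the whole dataset, complementing the most probable taxa.
    Returns a long table (topic, taxon, lift, amplification).
    """
    totals = corpus.data[model.vocab].sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = [t for t, n in zip(model.vocab, totals) if n == 0]
        raise ValueError(f"zero-frequency taxa in vocabulary: {bad[:5]}")
    freq = totals / totals.sum()
    lift = model.phi / freq[None, :]
    norm = lift / lift.sum(axis=1, keepdims=True)
    rows = []
    for k in range(model.K):
        for w, taxon in enumerate(model.vocab):
            rows.append({"topic": k, "taxon": taxon,
                         "lift": lift[k, w], "amplification": norm[k, w]})
    return pd.DataFrame(rows)


def trait_tests(
    values: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman rank correlation of each unit (topic or taxon column of
    ``values``) against each continuous trait, with Holm step-down control
    of the family-wise error rate over the whole unit x trait family.

    Missing trait values are dropped pairwise.  Constant vectors or fewer
    than ``min_pairs`` complete pairs make the test undefined; such rows
    are recorded with a reason and excluded from the Holm family.
    """
    if not values.index.equals(traits.index):
        raise ValueError("values and traits must share the same sample index")
    rows = []
    for unit in values.columns:
        for trait in traits.columns:
            v = values[unit].astype(float)
            t = traits[trait].astype(float)
            ok = v.notna() & t.notna()
            n = int(ok.sum())
            reason = ""
            rho = p = np.nan
            if n < min_pairs:
                reason = f"fewer than {min_pairs} complete pairs"
            elif v[ok].nunique() == 1 or t[ok].nunique() == 1:
                reason = "constant vector"
            else:
                res = stats.spearmanr(v[ok], t[ok])
                rho, p = float(res.statistic), float(res.pvalue)
            rows.append({"unit": unit, "trait": trait, "n": n,
                         "rho": rho, "p_raw": p, "reason": reason})
    df = pd.DataFrame(rows)
    valid = df["p_raw"].notna()
    df["p_holm"] = np.nan
    df["significant"] = False
    if valid.any():
        reject, p_adj, _, _ = multipletests(
            df.loc[valid, "p_raw"], alpha=alpha, method="holm"
        )
        df.loc[valid, "p_holm"] = np.minimum(p_adj, 1.0)
        df.loc[valid, "significant"] = reject
    return df


def estimate_null_fwer(
    n_replicates: int = 500,
    n_samples: int = 119,
    n_topics: int = 6,
    n_traits: int = 7,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Monte Carlo family-wise error rate of the Holm-corrected topic-trait
    testing procedure under a complete null.

    Each replicate draws Dirichlet topic proportions and independent
    Gaussian traits with no topic loading, runs all topic x trait Spearman
    tests with Holm step-down at level ``alpha``, and records whether any
    pair is flagged.  Returns the flagged-replicate fraction, its binomial
    Monte Carlo standard error, and the bound ``alpha + 3 se``.
    """
    from .synthetic import null_topic_trait_dataset

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        theta, traits = null_topic_trait_dataset(
            n_samples=n_samples, K=n_topics, n_traits=n_traits,
            seed=int(rng.integers(2**31)),
        )
        result = trait_tests(theta, traits, alpha=alpha)
        hits += int(result["significant"].any())
    fwer = hits / n_replicates
    se = math.sqrt(alpha * (1 - alpha) / n_replicates)
    return {
        "fwer": fwer,
        "mc_se": se,
        "bound": alpha + 3 * se,
        "n_replicates": n_replicates,
        "n_tests_per_replicate": n_topics * n_traits,
    }


def per_taxon_correlations(
    matrix: CountMatrix,
    traits: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman tests between per-sample taxon relative abundances and
    traits — the taxon-level counterpart of the topic-trait tests.

    Taxa absent from every sample are excluded with a reason row.
    """
    rel = matrix.data.div(matrix.data.sum(axis=1), axis=0)
    absent = [t for t in rel.columns if matrix.data[t].sum() == 0]
    present = [t for t in rel.columns if t not in absent]
    out = trait_tests(rel[present], traits.loc[rel.index], alpha=alpha)
    if absent:
        extra = pd.DataFrame([
            {"unit": t, "trait": tr, "n": 0, "rho": np.nan, "p_raw": np.nan,
             "reason": "taxon absent from every sample",
             "p_holm": np.nan, "significant": False}
            for t in absent for tr in traits.columns
        ])
        out = pd.concat([out, extra], ignore_index=True)
    return out
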