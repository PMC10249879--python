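"""Synthetic microbiome communities with planted topic structure.

Datasets are drawn from the same generative process LDA assumes: each
sample receives topic proportions theta from a Dirichlet prior that may
depend on its experimental condition levels, a sequencing depth, and
multinomial counts over the mixture of planted topic-taxa distributions.
Continuous traits are linear in a chosen topic's true proportion plus
Gaussian noise.  Full ground truth (phi, per-condition priors, loadings,
design, seeds) is recorded so recovery, association, and error-rate
properties can be tested without any external data.

The ``maize_like`` preset mirrors a two-generation greenhouse rhizosphere
design: 119 samples, factors generation (2) x watering (2) x watering
stability (2) x soil source (3), 500 taxa spread over a 27-phylum
taxonomy skeleton, 10 planted topics, depths 1,000-10,000.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleMetadata
from .taxonomy import RANKS, TaxonLineage


@dataclass
class TraitLoading:
    trait: str
    topic: int
    slope: float
    noise_sd: float


@dataclass
class SyntheticTruth:
    """Ground truth of a planted community: everything needed to regenerate
    the dataset byte-for-byte and to score recovery."""

    phi: np.ndarray                       # K x V planted topics
    base_alpha: np.ndarray                # length-K document prior
    condition_effects: dict[str, dict[str, np.ndarray]]
    # condition -> level -> per-topic multiplicative prior effect
    trait_loadings: list[TraitLoading]
    design: pd.DataFrame                  # per-sample condition labels
    seed: int
    taxon_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("planted phi rows must sum to 1")
        if (self.base_alpha <= 0).any():
            raise ValueError("alpha entries must be positive")
        for lo in self.trait_loadings:
            if lo.noise_sd < 0:
                raise ValueError(f"negative noise sd for trait {lo.trait!r}")
            if not 0 <= lo.topic < self.phi.shape[0]:
                raise ValueError(f"loading references missing topic {lo.topic}")

    @property
    def K(self) -> int:
        return self.phi.shape[0]

    @property
    def V(self) -> int:
        return self.phi.shape[1]

    def sample_alpha(self, sample: str | int) -> np.ndarray:
        """Document prior for one sample: base alpha times the product of
        its condition-level effects."""
        row = self.design.loc[sample]
        alpha = self.base_alpha.copy()
        for cond, effects in self.condition_effects.items():
            alpha = alpha * effects.get(str(row[cond]), np.ones(self.K))
        return alpha

    def expected_theta(self) -> pd.DataFrame:
        """Per-sample expected topic proportions under the planted priors
        (the normalized document alpha)."""
        rows = np.stack([
            (a := self.sample_alpha(s)) / a.sum() for s in self.design.index
        ])
        return pd.DataFrame(rows, index=self.design.index,
                            columns=[f"topic_{k}" for k in range(self.K)])


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    metadata: SampleMetadata
    truth: SyntheticTruth
    true_theta: pd.DataFrame


def simulate_design(
    n_samples: int,
    conditions: dict[str, list[str]],
    seed: int = 0,
    balanced: bool = True,
) -> pd.DataFrame:
    """Assign condition levels to samples in a near-balanced factorial.

    Every combination of levels appears either floor or ceil of
    n/combinations times; the leftover combinations are chosen at random.
    """
    for name, levels in conditions.items():
        if not levels:
            raise ValueError(f"condition {name!r} has no levels")
    combos = list(itertools.product(*conditions.values()))
    if balanced and n_samples < 2 * len(combos):
        raise ValueError(
            f"{n_samples} samples cannot cover {len(combos)} level "
            "combinations twice; pass balanced=False"
        )
    rng = np.random.default_rng(seed)
    reps = n_samples // len(combos)
    assigned = combos * reps
    leftover = n_samples - len(assigned)
    if leftover:
        extra_idx = rng.choice(len(combos), size=leftover, replace=False)
        assigned += [combos[i] for i in extra_idx]
    order = rng.permutation(len(assigned))
    rows = [assigned[i] for i in order]
    return pd.DataFrame(
        rows,
        columns=list(conditions),
        index=[f"S{i:04d}" for i in range(n_samples)],
    )


def separated_phi(K: int, V: int, seed: int = 0, background: float = 0.05) -> np.ndarray:
    """Well-separated planted topics: each topic concentrates (1-background)
    of its mass on its own block of V//K taxa, with a small shared
    background over the rest.  Pairwise cosine similarity stays low."""
    rng = np.random.default_rng(seed)
    phi = np.zeros((K, V))
    block = V // K
    for k in range(K):
        lo, hi = k * block, (k + 1) * block if k < K - 1 else V
        main = rng.dirichlet(np.full(hi - lo, 5.0))
        phi[k, lo:hi] = (1 - background) * main
        rest = np.setdiff1d(np.arange(V), np.arange(lo, hi))
        phi[k, rest] = background * rng.dirichlet(np.full(rest.size, 1.0))
    return phi / phi.sum(axis=1, keepdims=True)


def simulate_corpus(
    truth: SyntheticTruth,
    depth_range: tuple[int, int] = (1000, 10000),
    seed: int | None = None,
) -> SyntheticDataset:
    """Draw a count table from the planted generative process.

    Per sample: theta ~ Dirichlet(condition-specific alpha), depth uniform
    in ``depth_range``, counts multinomial over the theta-phi mixture.
    Traits follow the truth's loadings.  Identical truth and seed
    regenerate identical data.
    """
    lo, hi = depth_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid depth range")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sample_ids = list(truth.design.index)
    K, V = truth.K, truth.V
    taxa = truth.taxon_ids or [f"ASV{j:05d}" for j in range(V)]

    theta = np.empty((len(sample_ids), K))
    counts = np.empty((len(sample_ids), V), dtype=np.int64)
    for i, s in enumerate(sample_ids):
        theta[i] = rng.dirichlet(truth.sample_alpha(s))
        depth = int(rng.integers(lo, hi + 1))
        counts[i] = rng.multinomial(depth, theta[i] @ truth.phi)

    count_df = pd.DataFrame(counts, index=sample_ids, columns=taxa)
    true_theta = pd.DataFrame(
        theta, index=sample_ids, columns=[f"topic_{k}" for k in range(K)]
    )
    traits = simulate_traits(truth, theta, seed=seed + 1)
    metadata = SampleMetadata(conditions=truth.design.astype(str), traits=traits)
    return SyntheticDataset(
        counts=CountMatrix(count_df),
        metadata=metadata,
        truth=truth,
        true_theta=true_theta,
    )


def simulate_traits(
    truth: SyntheticTruth,
    theta: np.ndarray,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Continuous traits: slope * theta_topic + N(0, sd) for loaded traits.

    A zero slope gives a pure-noise (null) trait; ``missing_rate`` injects
    missing values completely at random.
    """
    rng = np.random.default_rng(seed)
    n = theta.shape[0]
    cols = {}
    for lo in truth.trait_loadings:
        noise = rng.normal(0.0, lo.noise_sd, size=n) if lo.noise_sd > 0 else 0.0
        cols[lo.trait] = lo.slope * theta[:, lo.topic] + noise
    df = pd.DataFrame(cols, index=truth.design.index)
    if missing_rate > 0:
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(mask)
    return df


def skeleton_taxonomy(
    taxon_ids: list[str],
    seed: int = 0,
    n_phyla: int = 27,
    n_classes: int = 63,
    n_orders: int = 152,
    n_families: int = 247,
    unknown_rate: float = 0.2,
) -> list[TaxonLineage]:
    """Random but hierarchy-consistent lineages over a fixed skeleton of
    phyla/classes/orders/families, with a fraction of ASVs truncated to an
    unknown rank so aggregation fallback paths are exercised.

    The skeleton sizes default to the richness of a temperate
    rhizosphere community (27 phyla, 63 classes, 152 orders, 247 families).
    """
    rng = np.random.default_rng(seed)
    class_phylum = rng.integers(0, n_phyla, size=n_classes)
    order_class = rng.integers(0, n_classes, size=n_orders)
    family_order = rng.integers(0, n_orders, size=n_families)
    lineages = []
    for asv in taxon_ids:
        fam = int(rng.integers(0, n_families))
        order = int(family_order[fam])
        cls = int(order_class[order])
        phy = int(class_phylum[cls])
        ranks: list[str | None] = [
            "Bacteria",
            f"Phylum{phy:02d}",
            f"Class{cls:02d}",
            f"Order{order:03d}",
            f"Family{fam:03d}",
            None,  # genus/species left unknown (typical for soil ASVs)
            None,
        ]
        if rng.random() < unknown_rate:
            cut = int(rng.integers(1, 5))  # truncate at phylum..family
            for j in range(cut, len(RANKS)):
                ranks[j] = None
        lineages.append(TaxonLineage(asv_id=asv, ranks=tuple(ranks)))
    return lineages


MAIZE_CONDITIONS = {
    "generation": ["G0", "G1"],
    "watering": ["HW", "FW"],
    "stability": ["ST", "SW"],
    "soil": ["AG", "FR", "PR"],
}
MAIZE_TRAITS = ["stem_height", "stem_diameter", "root_biomass",
                "LMA", "LWC", "Cond", "WUEi"]


def maize_like_truth(
    seed: int = 0,
    n_samples: int = 119,
    V: int = 500,
    K: int = 10,
    effect_fold: float = 4.0,
    trait_slope: float = 1.0,
    trait_noise_sd: float = 0.1,
    null_traits: bool = False,
) -> SyntheticTruth:
    """Ground truth shaped like a two-generation maize rhizosphere study.

    Plants an ``effect_fold``-to-1 ratio of expected topic proportion for
    half-watering on topic 0 and for generation 1 on topic 1 (the raw
    alpha multiplier is solved from the fold so the *normalized* prior
    mean moves by exactly that ratio), and loads two traits on topics 0
    and 1 (unless ``null_traits``, which zeroes every slope for
    error-rate studies).  V defaults to 500 taxa, a desk-scale stand-in
    for the ~4,000 ASVs of a real rhizosphere table.
    """
    if not effect_fold < K:
        raise ValueError("effect_fold must be smaller than K")
    rng = np.random.default_rng(seed)
    design = simulate_design(n_samples, MAIZE_CONDITIONS,
                             seed=int(rng.integers(2**31)), balanced=False)
    phi = separated_phi(K, V, seed=int(rng.integers(2**31)))
    effects = {
        "watering": {"HW": _topic_boost(K, 0, effect_fold)},
        "generation": {"G1": _topic_boost(K, 1, effect_fold)},
    }
    slope = 0.0 if null_traits else trait_slope
    loadings = [
        TraitLoading("stem_height", 0, slope, trait_noise_sd),
        TraitLoading("root_biomass", 1, slope, trait_noise_sd),
    ] + [TraitLoading(t, 0, 0.0, 1.0)
         for t in MAIZE_TRAITS if t not in ("stem_height", "root_biomass")]
    return SyntheticTruth(
        phi=phi,
        base_alpha=np.full(K, 0.5),
        condition_effects=effects,
        trait_loadings=loadings,
        design=design,
        seed=seed,
        taxon_ids=[f"ASV{j:05d}" for j in range(V)],
        sample_ids=list(design.index),
    )


def _topic_boost(K: int, topic: int, fold: float) -> np.ndarray:
    """Alpha multiplier m making the expected proportion of one topic
    ``fold`` times its unboosted value under a symmetric base prior:
    m K / (K - 1 + m) = fold  =>  m = (K - 1) fold / (K - fold)."""
    boost = np.ones(K)
    boost[topic] = (K - 1) * fold / (K - fold)
    return boost


def null_topic_trait_dataset(
    n_samples: int = 119,
    K: int = 6,
    n_traits: int = 7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A complete-null replicate for family-wise error studies: Dirichlet
    topic proportions and independent standard-normal traits with zero
    loading on every topic."""
    rng = np.random.default_rng(seed)
    idx = [f"S{i:04d}" for i in range(n_samples)]
    theta = pd.DataFrame(
        rng.dirichlet(np.ones(K), size=n_samples),
        index=idx, columns=[f"topic_{k}" for k in range(K)],
    )
    traits = pd.DataFrame(
        rng.normal(size=(n_samples, n_traits)),
        index=idx, columns=[f"trait_{t}" for t in range(n_traits)],
    )
    return theta, traits
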