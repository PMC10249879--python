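# Methods

## Model

`microtopics` fits latent Dirichlet allocation to a sample × taxon count
matrix. Each sample j has topic proportions θ_j ~ Dirichlet(α); each topic
k has a taxon distribution φ_k ~ Dirichlet(β); every read in sample j picks
a topic z ~ θ_j and a taxon w ~ φ_z. Topics are therefore sub-communities
that may overlap in membership, and a sample is a mixture of them — a
deliberately softer decomposition than clustering, suited to communities
whose composition shifts gradually with treatment.

Assumptions worth keeping in mind: reads are exchangeable within a sample
(no spatial or phylogenetic structure inside the count), sequencing depth
carries no biological signal (θ is depth-free), and the taxon distributions
φ are shared across all samples — treatments move topic *abundance*, not
topic *content*.

## Inference

Collapsed Gibbs sampling integrates out θ and φ and resamples each read's
topic assignment from

p(z_i = k | rest) ∝ (n_dk + α_k) · (n_kw + β) / (n_k + Vβ),

with the read itself excluded from all counts. Sampling order is document
order then token order, driven by a single PRNG stream seeded explicitly,
so a fit is bit-reproducible from (matrix, K, α, β, iterations, seed). The
inner loop is compiled with numba.

Point estimates come from the final Gibbs state with Dirichlet smoothing:
φ_kw = (n_kw + β)/(n_k + Vβ), θ_dk = (n_dk + α_k)/(n_d + Σα). This is the
convention of the widely used Gibbs-LDA toolchains; posterior averaging
over thinned states is deliberately not the default because averaging
across label-switching states blurs topics.

Progress is tracked as the collapsed joint log P(w, z | α, β) per token
(two Dirichlet-multinomial blocks), recorded every sweep for the first
1,000 sweeps and every 10th thereafter to bound trace memory at long runs.
The library default of 10,000 sweeps is generous for amplicon-scale tables;
the test suite uses 150–300 sweeps on small planted corpora, which the
recovery tests show is already enough there.

Defaults α_k = 5/K (symmetric, summing to 5) and β = 0.01 follow the same
toolchain convention. Held-out samples are scored by fold-in: φ frozen,
document-side assignments resampled with p(z=k) ∝ (n_dk + α_k)·φ_kw;
out-of-vocabulary taxa are dropped with a warning and a sample with no
in-vocabulary reads gets a uniform θ.

## Taxonomic aggregation

Lineages are ranked kingdom→species; a rank below the first unknown is
treated as unknown (prefix-known structure). At a target rank, an
identified lineage contributes to that rank's name; an unidentified one
contributes to `<rankcode>_<FinestKnownName>_NA` (codes k/p/c/o/f/g), and a
fully unknown lineage to `unclassified_NA`. This keeps unclassified
organisms in the analysis instead of silently shrinking the community.
Aggregation conserves per-sample totals exactly; the rare-taxon filter then
drops aggregated taxa with **total count across all samples < 4** (read as
a dataset-wide total — per-sample filtering would zero sparse columns
inconsistently). At the ASV level the filter is a no-op unless explicitly
requested. Genus/species aggregation is behind an `allow_deep` flag because
environmental tables are mostly unidentified there.

## Model selection metrics

- **Perplexity** exp(−Σ n_dw log Σ_k θ̂_dk φ_kw / N) on held-out samples,
  with θ̂ from fold-in. A model uniform over V taxa scores exactly V.
  Left-to-right estimation would be an alternative estimator; fold-in was
  chosen for simplicity and because only between-K comparisons matter.
- **Pairwise cosine similarity** between φ rows, mean over unordered pairs;
  undefined (flagged) at K = 1.
- **Coherence** (UMass variant): Σ_{m=2..M} Σ_{l<m}
  log[(D(v_m,v_l)+1)/D(v_l)] over a topic's top M = 10 taxa, D counting
  samples where a taxon occurs; rank ties broken by taxon label for
  determinism.
- **Exclusivity**: mean over a topic's top M taxa of
  φ_kw / Σ_k' φ_k'w (1 = owned by this topic, 1/K = shared evenly).
- **Effective number of words**: 1/Σ_w φ_kw², the inverse Simpson
  concentration; taxa ranked within ceil(ENW) are flagged as a topic's
  important members (ceiling chosen so a fractional ENW never excludes the
  taxon straddling the threshold).

`cross_validate_k` runs repeated k-fold CV (default 5 × 5) with perplexity
per held-out fold and the remaining metrics on one full-data fit per
repeat (they are properties of a fitted model, not of a split). All
sub-seeds derive from one master seed, so a report is reproducible.
Cross-run consistency uses optimal bipartite matching (Hungarian algorithm)
of topics between runs under cosine similarity.

## Association analysis

With θ rows summing to one, the per-level topic share
x_{i,t} = f_{i,t}/Σ_i f_{i,t} (f = summed θ over a level's samples) equals
the level's mean abundance of topic i. For two-level conditions the
weighting w_{i,t} = x_{i,t}/(x_{i,t1}+x_{i,t2}) is mapped to a plot
coordinate (1−2w)/w or (2w−1)/w, a continuous [−1, 1] scale with 0 at
parity. The strength classes — moderate at a ≥2× mean-abundance ratio,
strong at ≥4× — coincide algebraically with |coordinate| 0.5 and 0.75, and
with focal shares of 67% and 80%. Conditions with more than two levels use
the minimum ratio over all alternative levels; a zero alternative mean with
positive focal mean counts as strong but is annotated degenerate.

Relative amplification (lift) divides φ_kw by the taxon's overall corpus
frequency and renormalizes within topic, surfacing taxa over-represented in
a topic relative to the whole dataset even when their absolute probability
is small.

Trait analysis uses Spearman rank correlation (average ranks on ties,
two-sided p) for every unit × trait pair, with Holm step-down over the
whole family at one taxonomic level — matching how results are reported
per level — and missing trait values dropped pairwise. Pairs with fewer
than 3 complete observations or a constant vector are recorded with a
reason and excluded from the family rather than imputed.

## Synthetic communities

The generator is the inverse of the model: per sample, θ ~ Dirichlet of a
condition-dependent α, depth ~ uniform integer in a range, counts ~
multinomial over Σ_k θ_k φ_k. Condition effects multiply α components; a
planted "f-fold" effect solves m = (K−1)f/(K−f) so the *expected
proportion* of the boosted topic moves by exactly f:1 (a raw α multiplier
would be diluted by normalization). Traits are slope·θ_topic + N(0, sd);
zero slopes give exact null traits for error-rate studies. Planted topics
from `separated_phi` put 95% of each topic's mass on its own taxon block,
keeping pairwise cosine low so recovery is well-posed.

The `maize-like` preset: 119 samples; factors generation (2) × watering
(2) × stability (2) × soil source (3) in a near-balanced factorial; K = 10
topics over V = 500 taxa (a desk-scale stand-in for a ~4,000-ASV table —
the shape, sparsity handling, and code paths are preserved while fits run
in seconds); depths 1,000–10,000; 7 traits of which two are loaded;
taxonomy assigned over a 27-phylum / 63-class / 152-order / 247-family
skeleton with a 20% truncation rate so aggregation fallback paths are
exercised. The trait noise model (linear + Gaussian) is a testing
convention, not a claim about any real crop dataset.

What the generator does *not* emulate: sequencing error and chimeras,
compositional/copy-number artifacts, phylogenetic correlation between
taxa, overdispersion beyond the Dirichlet-multinomial, and real taxonomies.
Passing recovery tests therefore show the estimator is correct under its
own model, not that any real community is LDA-distributed.

## Numerical choices and degenerate inputs

- Probabilities are kept as smoothed count ratios, so φ and θ rows sum to
  1 to ~1e-15; validation tolerance is 1e-9.
- Report TSVs print 6 significant digits, making files byte-stable for a
  fixed model and re-writable without drift.
- K = 1 degenerates cleanly: θ ≡ 1, φ the smoothed corpus frequency;
  cosine and exclusivity are flagged undefined rather than faked.
- A sample left empty by filtering is retained and flagged, but fitting
  refuses zero-total samples by name.
- Holm-adjusted p-values are clipped at 1; adjusted p is monotone in raw p
  by construction.

## Known limitations

- Collapsed Gibbs gives one posterior mode; very weakly separated topics
  can land in different modes across seeds (this is what the cross-run
  matching diagnostic is for).
- Perplexity via fold-in slightly underestimates the true held-out value
  at small iteration counts; comparisons across K remain valid because the
  bias is shared.
- The association classes use fixed 2×/4× ratio thresholds with no
  uncertainty statement; they are descriptive, not tests.
- No BIOM-HDF5 reader; the sparse carrier is a plain 3-column TSV triplet
  table.
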