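"""Collapse an ASV table to higher taxonomic ranks.

Environmental ASVs are often unidentified below class or order; instead of
dropping them, they aggregate under their finest known rank with a
"<rankcode>_<Name>_NA" fallback label, and very rare aggregated taxa
(total count < 4) are filtered out.
"""

import microtopics as mt

truth = mt.maize_like_truth(seed=3, n_samples=40, V=300, K=5, effect_fold=3.0)
ds = mt.simulate_corpus(truth, depth_range=(500, 1500), seed=3)
lineages = mt.skeleton_taxonomy(ds.counts.taxon_ids, seed=3, unknown_rate=0.3)

print(f"input: {ds.counts.n_taxa} ASVs")
for level in ("family", "order", "class", "phylum"):
    agg = mt.aggregate_counts(ds.counts, lineages, level)
    kept = mt.filter_rare_taxa(agg, min_total=4)
    fallback = [t for t in kept.base.taxon_ids if t.endswith("_NA")]
    print(f"{level:>7}: {agg.base.n_taxa:3d} labels "
          f"({len(fallback)} fallback), {kept.base.n_taxa:3d} after <4 filter; "
          f"totals conserved: "
          f"{(agg.base.sample_totals() == ds.counts.sample_totals()).all()}")
print("example fallback labels:", fallback[:3])
# label counts shrink toward phylum level; per-sample read totals never
# change during aggregation, only the rare-taxon filter removes counts.
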