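"""Preprocess a community and compute per-year functional diversity.

Applies the inclusion rules (rare-taxon removal, ln(x+1) transform),
builds the Gower-Podani trait dissimilarity, and computes species
richness (SRic), trait richness (TRic), functional evenness (FEve) and
functional dispersion (FDis) for every sampled year.
"""
import traitflux as tf

cts, tm, _ = tf.generate_community(tf.SyntheticConfig(seed=2))
cts = tf.filter_rare_taxa(cts)              # <5% occurrence, never consecutive
cts_ln = tf.ln_transform(cts)               # ln(x+1) density weights
tm = tm.subset(cts.taxa)

dm = tf.gower_distance(tm)
print(f"Gower-Podani distances: {dm.shape[0]} taxa, "
      f"range [{dm.data.min():.3f}, {dm.data.max():.3f}]")

div = tf.diversity_series(cts_ln, tm, dm=dm)
print(div.head(5).round(3).to_string(index=False))
# SRic/TRic count present taxa and expressed trait categories; FEve in
# [0,1] measures how evenly ln-density spreads along the trait-space
# minimum spanning tree; FDis is the weighted mean distance to the
# community's weighted centroid in trait space.
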