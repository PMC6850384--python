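"""Generate a synthetic monitoring community and inspect its structure.

The generator mimics multi-decadal coastal monitoring data: log-normal
densities driven by shared latent trends, fuzzy-coded traits, a few
missing sampling years and a set of rare, non-established taxa.
"""
import traitflux as tf

cfg = tf.SyntheticConfig(
    n_years=40, n_taxa=30, n_latent_trends=2,
    rare_taxon_fraction=0.1, missing_years=(12, 27), seed=1,
)
cts, tm, truth = tf.generate_community(cfg)

print(f"community: {cts.n_sampled_years} sampled years x {len(cts.taxa)} taxa")
print(f"missing years: {cts.missing_years}")
print(f"rare (non-established) taxa: {truth['rare_taxa']}")
print("trait blocks:", [(b.name, len(b.categories), b.kind) for b in tm.blocks])
print("trait validation problems:", tf.validate_trait_matrix(tm) or "none")
print(cts.density.iloc[:3, :4].round(2))
# Each density cell is a yearly mean catch/abundance; rare taxa have
# zero density except in one or two non-consecutive years.
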