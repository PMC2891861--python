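"""Hypergeometric pathway over-representation on synthetic gene sets.

Simulates a universe of 500 quantified proteins with a 40-protein
significant list, builds ten gene sets of which two are loaded with
significant proteins, and tests each set with the upper-tail hypergeometric
probability against the quantified background.
"""

from nrfomics import enrich, simulate

universe = [f"SIM{i:05d}" for i in range(500)]
significant = universe[:40]
sets = simulate.simulate_gene_sets(
    universe, n_sets=10, set_size=25,
    enriched_in=significant, n_enriched_sets=2, enrichment_fraction=0.4,
    seed=8)
results = enrich.hypergeom_enrich(significant, universe, sets)
print(results[["set_name", "set_size", "overlap", "p", "neg_log10_p"]]
      .to_string(index=False))
# the two loaded sets (set000, set001) should dominate with the smallest
# upper-tail p-values; p = P(overlap >= k) under random draws of the
# significant list from the quantified universe
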