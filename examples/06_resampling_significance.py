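"""Resampling-based significance of the linked-correlation statistic.

Two simulations: a null ensemble of randomly placed links (spread of the
genome-wide mean at the observed link count) and a 50% bootstrap over the
measured links (sampling stability of the observed statistic).  Their
separation in null standard deviations summarizes the significance.
"""

import chromexpr as cx

params = cx.GeneratorParams(
    n_modules=15, module_size=10, rho_linked=0.3, lognormal_shift=0.15,
    contact_background_rate=0.0, module_contact_rate=0.3, seed=11)
ds = cx.generate_dataset(params)
expr = cx.normalize_samples(ds.expression)
links = cx.build_gene_links(ds.contacts, ds.annotation, min_count=1)

observed = cx.linked_vs_background(links, expr, ds.annotation).mean_linked
null = cx.random_link_null(expr, ds.annotation, n_links=len(links),
                           n_reps=1000, seed=5)
boot = cx.bootstrap_links(links, expr, frac=0.5, n_reps=1000, seed=6)

print(f"observed mean linked correlation: {observed:.4f}")
print(f"random-link null: mean {null.summary_mean:.4f}, sd {null.summary_sd:.4f}")
print(f"bootstrap (50% of links): mean {boot.summary_mean:.4f}, "
      f"sd {boot.summary_sd:.4f}, skewness {boot.skewness:.2f}")
print(f"separation: {cx.zscore_separation(null, observed):.1f} null sd")
print("# the observed statistic sits far outside the null ensemble, and the")
print("# bootstrap spread shows it is stable under halving the link data")
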