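"""Standard OTU-table processing: rarefaction, singleton removal, filters.

The canonical order is rarefy -> remove singletons -> (relative abundance,
top-N subsets, prevalence curation).  Numbers printed are counts of OTUs
surviving each step.
"""

import marshtransplant as mt

table, metadata, sites, _ = mt.simulate_experiment(mt.default_config(seed=7, depth=8000))
print(f"raw table: {table.n_otus} OTUs x {table.n_samples} samples, "
      f"depth {table.sample_totals().min()}-{table.sample_totals().max()}")

rarefied = mt.rarefy(table, depth=5000, seed=1)
print(f"after rarefying to 5,000 reads: every sample at depth "
      f"{set(rarefied.sample_totals().tolist())}")

no_singletons, n_removed = mt.remove_singletons(rarefied)
print(f"singleton removal: {n_removed} OTUs with a single read dropped, "
      f"{no_singletons.n_otus} kept (sum = {rarefied.n_otus})")

prevalent = mt.prevalence_filter(no_singletons, 0.95)
print(f"prevalence curation (> 95% of {no_singletons.n_samples} samples, "
      f"i.e. >= {mt.prevalence_integer_threshold(no_singletons.n_samples, 0.95)}): "
      f"{prevalent.n_otus} OTUs remain")

top10 = mt.top_n_otus(no_singletons, 10)
rel = mt.relative_abundance(top10)
print(f"top-10 subset: {top10.otu_ids}")
print("their pooled share of sample 1:",
      round(top10.counts[:, 0].sum() / 5000, 3))

# per-sample share of one OTU's grand total (the indicator scan's y variable)
shares = mt.otu_percent_of_total(no_singletons, no_singletons.otu_ids[0])
print(f"{no_singletons.otu_ids[0]} max per-sample share of its own total: "
      f"{100 * shares.max():.1f}% (shares sum to {shares.sum():.3f})")
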