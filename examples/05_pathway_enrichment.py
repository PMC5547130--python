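"""Direction-aware pathway over-representation with activation z-scores.

Scores gene sets against the consensus differential proteins by the
right-tailed Fisher exact test with one Benjamini-Hochberg correction
across sets, and summarises direction concordance as the activation
z-score z = (concordant - discordant) / sqrt(annotated overlap).
"""

from plexde import (
    SyntheticConfig,
    build_master_table,
    generate_cohort,
    generate_genesets,
    run_differential,
    run_enrichment,
)
from plexde.quantify import rollup_experiment

config = SyntheticConfig(seed=1)
designs, tables, truth = generate_cohort(config)
sets = generate_genesets(truth, n_sets=12, set_size_range=(10, 25),
                         enrichment_fraction=1.0, seed=2, n_enriched=4)

records = {c: {d.experiment_id: rollup_experiment(t, d.reference_channel(c))
               for d, t in zip(designs, tables)} for c in ("low", "high")}
master_low = build_master_table(records["low"], designs, "low")
master_high = build_master_table(records["high"], designs, "high")
diff = run_differential(master_low, master_high)

result = run_enrichment(diff, sets, neglog_threshold=1.3)
print(result[["set_name", "k", "K", "neg_log10_bh", "z", "significant"]]
      .head(6).to_string(index=False))
print(f"\nplanted-enriched sets: {truth.enriched_set_names}")
# sets built from the planted proteins score far above the -log10(B-H) >= 1.3
# cutoff with strongly positive z (observed directions match the planted
# ones); random sets stay near p = 1 and carry no z-score.
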