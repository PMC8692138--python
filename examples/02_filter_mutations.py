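"""Consensus-filter a mutation table and summarize per-tumor burden.

Simulates a MAF-like table for 8 tumors where 40% of records are
intended deleterious, then applies the SIFT+PolyPhen consensus
(truncating variants deleterious by rule, synonymous never), aggregates
to genes, and reports recurrence and per-tumor means +/- SEM.
"""

from tumorcross import (
    aggregate_by_gene,
    classify_frame,
    make_genome,
    recurrent_genes,
    simulate_mutations,
    summarize_per_tumor,
)

genome = make_genome(1, 300_000, 25, 600, 5000, seed=11)
table, hidden_truth = simulate_mutations(
    genome, n_tumors=8, mutations_per_tumor=40, deleterious_fraction=0.4, seed=11
)

classified = classify_frame(table, consensus_mode="sift_and_polyphen")
agreement = (classified["deleterious"].to_numpy() == hidden_truth).mean()
print(f"records: {len(classified)}, deleterious: {int(classified['deleterious'].sum())}")
print(f"agreement with the generator's hidden labels: {agreement:.0%}")

gene_table = aggregate_by_gene(classified)
print(f"\ndeleteriously mutated genes: {gene_table.n_genes}")
for frac in (0.375, 0.5):
    genes = recurrent_genes(gene_table, frac)
    print(f"  mutated in >= {frac:.1%} of tumors: {len(genes)} genes")

_, summary = summarize_per_tumor(classified)
print("\nper-tumor burden (mean to one decimal, SEM = sd/sqrt(n)):")
for row in summary.to_dict("records"):
    print(f"  {row['metric']:>22}: {row['mean_1dp']:>6} +/- {row['sem']:.1f}")
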