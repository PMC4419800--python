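"""Ribosome density (translational efficiency) per chromosome.

Simulates paired ribo-seq/RNA-seq counts with a 1.3x density effect on X,
applies the stringent cutoffs (counts > 10/50, RPKMs > 2/5, strict
inequalities), and compares per-gene ribo/RNA RPKM ratios across
chromosomes.
"""

import chromstab as cs

params = cs.SyntheticParams(seed=11)
table, _ = cs.generate_gene_table(params)
ribo, rna = cs.generate_ribo_dataset(params, table)

records = cs.build_ribo_table(table, ribo, rna)
kept, removed = cs.apply_filters(records, cs.FilterThresholds())
dens = cs.add_density(kept)
result = cs.density_by_chromosome(dens)

print(f"records in: {len(records)}, kept after filters: {len(kept)}")
print("removed per rule:", dict(removed))
row = {s.chromosome: s for s in result.summaries}
print(f"\nmean density  A: {row['A'].mean:.3f}   X: {row['X'].mean:.3f}")
print(f"X:A density ratio = {result.xa_ratio:.3f} (planted effect 1.3)")
print(f"X vs A p = {result.xa_test.p_value:.3g} "
      f"(corrected: {result.xa_test_corrected.p_value:.3g})")
print("-> X-linked transcripts carry more ribosomes per transcript,")
print("   consistent with translational upregulation of the X.")
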