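"""Per-chromosome half-life statistics and the X:AA stability ratio.

Simulates the default world (353 X-linked genes, 11,326 autosomal genes,
1.46x X-stability effect, no assay cap) and summarises transcript
half-lives per chromosome.
"""

import chromstab as cs

params = cs.SyntheticParams(seed=42, halflife_cap_h=None)
table, truth = cs.generate_gene_table(params)

summaries = cs.chromosome_summary(table, "half_life_h")
print("chromosome   n      mean   median   95% CI")
for s in summaries:
    if s.chromosome in ("1", "13", "19", "A", "X"):
        print(f"{s.chromosome:>10} {s.n:>5} {s.mean:>8.2f} {s.median:>8.2f}"
              f"   [{s.ci_low:.2f}, {s.ci_high:.2f}]")

ratio = cs.xaa_ratio(table)
test = cs.x_vs_autosomes_test(table, n_comparisons=23 * 22 // 2)
print(f"\nX:AA half-life ratio = {ratio:.3f} (planted effect 1.46)")
print(f"X vs pooled autosomes, Kruskal-Wallis corrected p = {test.p_value:.3g}")
print("-> X-linked transcripts are markedly more stable than autosomal ones;")
print("   the ratio recovers the planted multiplicative effect.")
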