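"""Paired-condition deltas and housekeeping stratification.

Simulates a control/knockdown half-life pair (global destabilisation 0.65x,
an extra 0.9x on the X) and the housekeeping split, asking whether the X
effect depends on gene function or survives a global perturbation.
"""

import chromstab as cs

params = cs.SyntheticParams(seed=8, halflife_cap_h=None)
table, _ = cs.generate_gene_table(params)

pair = cs.generate_condition_pair(params, table,
                                  global_destabilization=0.65,
                                  x_extra_effect=0.9)
delta = cs.paired_condition_delta(pair, table).set_index("chromosome")
print("per-chromosome mean delta (treatment - control), hours:")
print(delta.loc[["1", "19", "A", "X"], "mean_delta"].round(3).to_string())
print(f"\nglobal means: control {delta.loc['A', 'mean_control']:.2f} h -> "
      f"treatment {delta.loc['A', 'mean_treatment']:.2f} h")
print("-> the X loses the most stability: the compartment with the planted")
print("   extra effect shows the most negative paired delta.")

strat = cs.stratify_housekeeping(table)
print("\nmean half-life by compartment and housekeeping flag:")
for (comp, flag), cell in sorted(strat.cells.items()):
    label = "housekeeping" if flag else "non-housekeeping"
    print(f"  {comp} {label:>16}: {cell.mean:.2f} h (n={cell.n})")
print("-> X exceeds A within both strata: the stability effect is not a")
print("   by-product of housekeeping-gene content.")
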