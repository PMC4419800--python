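"""Sliding-window half-life profiles along chromosome arms.

Computes 30-gene windows (1-gene step) along each arm and locates the
window centred on a chosen gene — the same manoeuvre used to inspect the
neighbourhood of a locus such as the X-inactivation centre.
"""

import chromstab as cs

params = cs.SyntheticParams(seed=3, halflife_cap_h=None)
table, truth = cs.generate_gene_table(params)

profiles = cs.sliding_window_profile(
    table, "half_life_h", window_size=30, step=1,
    arm_boundaries=truth["arm_boundaries"],
)

x_profiles = [p for p in profiles if p.chromosome == "X"]
for prof in x_profiles:
    means = [w.mean for w in prof.windows]
    print(f"chrX arm {prof.arm}: {len(prof.windows)} windows, "
          f"mean range [{min(means):.2f}, {max(means):.2f}] h")

query = x_profiles[1].gene_order[len(x_profiles[1].gene_order) // 2]
loc = cs.locate_gene_window(profiles, query)
print(f"\ngene {query} sits at the centre of window {loc.window_index} "
      f"on arm {loc.chromosome}{loc.arm} (edge-clamped: {loc.at_edge})")
print("-> window means smooth gene-level noise; no single region of the")
print("   chromosome drives the elevated average in this synthetic world.")
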