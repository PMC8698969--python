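"""Synthetic panels with planted inefficiency, checked two independent ways.

Generates a seeded panel of mutually non-dominated frontier units plus
units made inefficient by scaling inputs up and outputs down by a known
factor, then compares the GDEA classification at small alpha (union
deviation rule) against a brute-force dominance scan.
"""

from gdeastem import (
    GDEAConfig,
    SyntheticSpec,
    evaluate_all,
    fdh_dominance_efficient,
    generate_synthetic,
)

spec = SyntheticSpec(n_frontier=6, n_dominated=4, m=2, s=3, seed=42)
panel, truth = generate_synthetic(spec)

oracle = fdh_dominance_efficient(panel)
cfg = GDEAConfig.fdh(alpha=1e-4, dtilde_convention="union_max")
gdea = [s.is_alpha_efficient for s in evaluate_all(panel, cfg)]

print(f"{'unit':>4} {'planted':<9} {'dominance scan':<15} {'GDEA small-alpha':<16} parent")
for i, label in enumerate(panel.labels):
    parent = truth.parent.get(i)
    print(f"{label:>4} {'dominated' if truth.dominated[i] else 'frontier':<9} "
          f"{'efficient' if oracle[i] else 'inefficient':<15} "
          f"{'efficient' if gdea[i] else 'inefficient':<16} "
          f"{panel.labels[parent] if parent is not None else '-'}")

assert gdea == oracle
print("\nThe LP classification and the pairwise scan agree on every unit:")
print("all planted units are caught, no frontier unit is falsely flagged.")
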