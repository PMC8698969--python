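"""Frontier targets: what an inefficient hospital should aim for.

Takes hospital 1's optimal peer weights from the envelopment LP and maps
them back to the raw scale: the lambda-weighted average of its peers'
actual inputs and outputs, rounded to integers, is the attainable
operating point that would make hospital 1 efficient.
"""

from gdeastem import (
    GDEAConfig,
    hospital_panel,
    hospital_panel_normalized,
    project_to_frontier,
    solve_dual,
)

raw = hospital_panel()
norm = hospital_panel_normalized()
sol = solve_dual(norm, 0, GDEAConfig.fdh(dtilde_convention="zero"))
proj = project_to_frontier(raw, sol.lam, rounding="nearest_integer")

print("hospital 1 today:   inputs", raw.inputs[0].tolist(),
      " outputs", raw.outputs[0].tolist())
print("frontier target:    inputs", proj.target_inputs.tolist(),
      " outputs", proj.target_outputs.tolist())
print("peer weights:", {raw.labels[j]: round(w, 3) for j, w in proj.ref_weights.items()})
print()
print("Reading: cut average length of stay 168 -> 165 hours and OT/PT")
print("charges 217 -> 202, while raising severe/semi-severe/mild patient")
print("throughput to the printed targets, and hospital 1 joins the frontier.")
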