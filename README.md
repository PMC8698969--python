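# gdeastem

Generalised data envelopment analysis (GDEA) with an interactive STEM
loop for frontier target setting — built around a case study of 14
hospitals providing stroke care services.

## The problem

A hospital (a *decision-making unit*, DMU) consumes inputs — average
length of stay (ALOS, hours) and occupational/physical-therapy charges —
to produce outputs: severe, semi-severe and mild patients treated per
provider.  Data envelopment analysis asks which units sit on the
empirical production frontier and, for those that do not, which convex
combination of peers they should emulate.  Classical DEA, however,
ignores managerial preferences: the projection it proposes may be
operationally unacceptable.  This package closes that gap by rewriting
the DEA dual as a multi-objective linear program and letting a
decision-maker steer the projection interactively.

## The model

For a focal unit *o* with normalised data, the GDEA multiplier (primal)
problem maximises the score Δ_o over output weights *u* and input
weights *v*:

```
max Δ_o
s.t. Δ_o ≤ d̃_j + α [ Σ_r u_r (y_ro − y_rj) + Σ_i v_i (x_ij − x_io) ]   ∀j
     Σ u + Σ v = 1,   u_r ≥ ε,  v_i ≥ ε
```

where d̃_j keeps only the largest input/output difference against peer
*j* and ε is the non-Archimedean weight floor (ε ≤ 1/(m+s)).  The scale
parameter α unifies the classical models: small α gives the
free-disposal hull (FDH), large α the variable-returns BCC model, and
large α plus the ratio constraint Σu_r y_ro − Σv_i x_io = 0 (the free
dual variable *T*) the constant-returns CCR model.  The envelopment
(dual) problem

```
min ω − ε (Σ t^y + Σ t^x)
s.t. Σ_j [α(y_ro − y_rj) + d̃_rj] λ_j − ω + t^y_r + T·y_ro = 0   ∀r
     Σ_j [α(−x_io + x_ij) + d̃_ij] λ_j − ω + t^x_i − T·x_io = 0  ∀i
     Σ λ = 1,  λ, t ≥ 0
```

yields the efficiency value ω ≤ 0, the reference set (support of λ) and,
through the raw-scale convex combination Σ λ_j x_j / Σ λ_j y_j, the
frontier target.  The unit is α-efficient iff ω = 0 with all slacks
zero.  Treating the s output rows as objectives over the λ simplex turns
the dual into a multi-objective LP whose max-ordering scalarisation
recovers ω exactly; the STEM (step method) loop then minimises the
weighted Tchebychev distance to the ideal point and lets the
decision-maker relax chosen objectives by stated amounts Δf per
iteration until a most preferred solution (MPS) is accepted.

## Worked example

```python
from gdeastem import (GDEAConfig, evaluate_all, hospital_panel,
                      hospital_panel_normalized, project_to_frontier)

norm = hospital_panel_normalized()          # published normalised panel
config = GDEAConfig.fdh(alpha=1.0, epsilon=1e-6, dtilde_convention="zero")
sols = evaluate_all(norm, config, data_source="as_given")
print([s.label for s in sols if not s.is_alpha_efficient])
# ['1', '2', '3', '4', '6', '7', '8', '11']
print(round(sols[0].omega, 5))
# -0.00525
proj = project_to_frontier(hospital_panel(), sols[0].lam, rounding="nearest_integer")
print(proj.target_inputs.tolist(), proj.target_outputs.tolist())
# [165.0, 202.0] [246.0, 304.0, 296.0]
```

Eight of the fourteen hospitals are inefficient.  Hospital 1's ω of
−0.00525 says a convex mix of hospitals 5, 12 and 13 (weights 0.042,
0.561, 0.397) beats it everywhere; on the raw scale that mix means
cutting ALOS from 168 to 165 hours and charges from 217 to 202 while
raising all three patient throughputs.  The `examples/` directory walks
through each capability — evaluation, target setting, the MOLP bridge,
a scripted three-round STEM session, and synthetic benchmarking — as
short runnable scripts; the same pipeline is available from a shell via
the `gdea eval`, `gdea stem` and `gdea simulate` commands.

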