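# Methods

## Model family

The package implements generalised DEA (GDEA): a single LP family whose
scale parameter α > 0 spans the classical frontiers.  As α → 0 the
comparison term α·(weighted input/output differences) vanishes and only
the per-peer deviation quantity d̃ matters, recovering free-disposal-hull
(FDH) logic; as α grows the weighted differences dominate and the model
behaves like the additive variable-returns (BCC) model; adding the ratio
constraint Σu_r y_ro − Σv_i x_io = 0 — equivalently freeing the dual
variable T — yields constant returns (CCR).  "Sufficiently" small/large
is not knowable in advance, so `classification_sweep` reports how the
efficient set moves across α decades; the presets use α = 1 (FDH, the
value used in the hospital case study), α = 10³ (BCC) and α = 10³ with
free T (CCR).

All models run on column-normalised data (each input/output column
divided by its Euclidean norm over the n units), which bounds every
entry in [0, 1] and makes α and ε scale-free.

## Deviation conventions

The deviation quantity d̃ is defined loosely in the source formulations,
and its arrangement materially changes the LP.  Four explicit
conventions are implemented (`Convention`):

- **column_max** (default): per peer column, keep the largest output
  difference at its own position, and separately the largest input
  difference.  This is the formal matrix definition, and it makes the
  primal and dual exact LP duals when the primal expands d̃_j as
  u·(max output diff) + v·(max input diff).
- **cumulative_max**: entry (r, j) is the running maximum of the first r
  output differences (resp. first i input differences).  The worked
  hospital-1 coefficients (0.2548, 0.0542, −0.0863, 0.116, 0.1057) are
  only consistent with this arrangement, so it is the convention for
  reproducing that arithmetic.
- **union_max**: one selected difference per peer across outputs *and*
  inputs jointly — the primal's own selection rule.  Under it, and only
  under it, small-α efficiency coincides *exactly* with pairwise
  dominance: a non-dominated unit has a strictly positive selected entry
  in every peer column, forcing ω = 0 with zero slacks, while a
  dominated unit's parent column is entirely negative.  Under column_max
  a convex mixture of an "output specialist" and an "input specialist"
  peer can weakly dominate a non-dominated unit in d̃ space, perturbing
  ω by O(α); the dominance-equivalence test suite therefore runs
  union_max.
- **zero**: all deviation entries zero — the purely additive model, i.e.
  the large-α limit at unit scale.  This is the only arrangement that
  reproduces the published hospital efficiency table (ω₁ = −0.00525 vs
  the printed −0.00521, the same eight inefficient hospitals, and the
  same unit-1 reference set {5, 12, 13} with near-identical weights);
  with α = 1 under either of the first two conventions hospital 1 comes
  out efficient.  Reproduction runs and the case-study examples use
  `zero`.

Ties in every maximum are broken deterministically: outputs before
inputs, then lowest index.  (One source listing indexes a kept output
component inconsistently; the rule here is always "largest component at
its own position".)  One printed deviation value (d̃₃,₁₄ stated as
0.1274) contradicts its own printed coefficient (−0.0863 requires
0.0271); the coefficient is taken as authoritative.

## Numerical choices

- All LPs are solved with scipy's HiGHS interface; problems have at most
  n + s + m + 2 variables (≤ 20 for the case study).
- ε defaults to 10⁻⁶, far below the feasibility ceiling 1/(m+s) (= 0.2
  for the hospital panel).  ε = 1/(m+s) pins all weights to ε; larger
  values make the multiplier LP infeasible and raise a dedicated error.
- Classification tolerance `tol_zero` = 10⁻⁷ on |ω| and on each slack;
  ω is the reported efficiency, the full objective ω − εΣt is stored
  separately.  Strong duality |Δ* − (ω* − εΣt*)| holds to ~10⁻¹⁶ because
  the two problems are built from the same coefficient matrices.
- Alternative optimal λ bases exist; the solver's basis is reported
  as-is, and tests assert ω, classification and projection feasibility
  rather than λ identity.
- Raw-scale projection targets round half-up (`floor(x + 0.5)`),
  matching integer patient counts.

## Normalised-table caveat

The published normalised table's *input* columns equal the Euclidean
normalisation of the raw inputs at printed precision only for some cells
(the ALOS cells of hospitals 11 and 14 reproduce exactly; the charges
column differs in the fourth decimal), and its *output* columns are not
the normalisation of the raw outputs at all.  The table is therefore
embedded verbatim as the canonical input for reproducing the published
efficiency values and worked coefficients, and no attempt is made to
reverse-engineer its provenance.  `euclidean_normalize` is the operation
intended for fresh raw data.

## The MOLP bridge and STEM

The dual's s output rows, read as objectives f_r(λ) over the λ simplex
with the m input rows as constraints, form a multi-objective LP.  Its
max-ordering scalarisation (minimise an auxiliary ω bounding every row)
is the dual re-derived, so ω agrees with the envelopment optimum; the
test suite checks this to 10⁻⁸ on the case study and on 20 seeded
synthetic panels, comparing against the dual re-solved with a vanishing
ε (the scalarisation carries no slack reward).

STEM runs in minimisation orientation (the published statement is the
maximisation mirror image): the ideal point collects each objective's
minimum over the feasible region, the payoff table evaluates all
objectives at each single-objective minimiser, and the estimated nadir
is the column-wise worst.  Design choices the source leaves open:

- **Weights**: w_i ∝ (nadir_i − ideal_i)/max(|nadir_i|, 10⁻⁹),
  normalised to sum to 1 — the classic STEM relative-range weighting.
  When a nadir component is ≈ 0 this inflates that objective's weight;
  with all-negative ideal values (as here) the weighting still orders
  objectives by range.
- **Input bound ω̄**: during preference exploration the input rows are
  bounded by ω̄ = 0 by default (iterates stay within the
  frontier-feasible region); any other bound, e.g. the unit's own dual
  ω*, can be set when building the MOLP.
- **Bookkeeping**: relaxed objectives are capped at (previous value +
  Δf), leave the Tchebychev block permanently (weight zeroed, remaining
  weights renormalised), and every non-relaxed objective is capped at
  its previous value, so maintained objectives never worsen.  Because
  the previous iterate always satisfies the new constraints, a step is
  infeasible only if the feasible region itself is empty (e.g. an
  unreachable ω̄), which raises an explicit error.
- **Δf scale**: relaxations may be stated on the objective scale or in
  raw output units; the latter are divided by the raw column's Euclidean
  norm (and multiplied by α) to reach the objective scale.
- **Per-iterate efficiency**: the "induced efficiency" reported for an
  iterate is max over all objective and input rows at λ — a defined,
  reproducible surrogate that equals ω at the max-ordering optimum.  The
  per-iteration efficiency values printed in the source case study
  depend on an unspecified weight formula and are not reproduction
  targets; the scripted walk here reproduces the qualitative behaviour
  (induced efficiency non-increasing toward zero, acceptance after three
  rounds).

## Synthetic panels

`generate_synthetic` emulates the case-study structure: frontier units
with log-uniform inputs on [100, 300] and outputs either from a
decreasing-returns Cobb–Douglas technology with random exponents
(`cobb_douglas`) or drawn independently (`random_nondominated`), kept
pairwise non-dominated by rejection sampling; plus planted inefficient
units built from a random frontier parent with inputs × u and outputs
÷ u, u ~ Uniform(1.05, 1.5], hence strictly dominated by construction.
Defaults (6 frontier + 4 dominated units, m = 2, s = 3) mirror the
hospital panel's scale.  What the generator does *not* emulate: noise in
the data, correlated inputs, zero entries, or units near-but-off the
frontier — so passing tests demonstrate correctness of the LP machinery
and classification logic, not robustness to measurement error.

## Known limitations

- The published efficiency table is matched to ~1% on ω₁ but not to the
  printed digit (−0.00525 vs −0.00521), and three of the eight printed
  inefficient ω values differ by more (their λ rows match; the source's
  solver or data precision likely differs).  One printed value
  ("−0006.73" for hospital 3) is garbled and excluded from comparison.
- FDH-dominance equivalence at finite small α is exact only under the
  union_max convention; under column_max it holds up to O(α) boundary
  cases.
- No super-efficiency, cross-efficiency, window analysis, non-radial or
  imprecise-data extensions; no missing-data handling.
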