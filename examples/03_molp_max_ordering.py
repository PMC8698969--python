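"""From the envelopment dual to a multi-objective program, and back.

Builds the s-objective linear program over the peer simplex for hospital 1
(cumulative deviation convention, the one the worked coefficients follow),
prints a few of its coefficients, and shows that minimising the
max-ordering auxiliary variable recovers the envelopment optimum omega.
"""

from gdeastem import (
    GDEAConfig,
    hospital_panel_normalized,
    max_ordering_solve,
    solve_dual,
    to_molp,
)

norm = hospital_panel_normalized()

molp = to_molp(norm, 0, GDEAConfig.fdh(dtilde_convention="cumulative_max"))
print("objective 1 coefficients on lambda_2 and lambda_14:",
      round(molp.obj_rows[0, 1], 4), round(molp.obj_rows[0, 13], 4))
print("objective 3 coefficient on lambda_14:", round(molp.obj_rows[2, 13], 4))
print("input row 2 coefficient on lambda_14:", round(molp.in_rows[1, 13], 4))

cfg = GDEAConfig.fdh(dtilde_convention="zero", epsilon=1e-14)
omega_mo, lam = max_ordering_solve(to_molp(norm, 0, cfg))
omega_dual = solve_dual(norm, 0, cfg).omega
print(f"\nmax-ordering omega = {omega_mo:.6f}, envelopment omega = {omega_dual:.6f}")
print("The two coincide: the scalarised multi-objective program and the")
print("envelopment dual are the same problem, which is what lets an")
print("interactive multi-objective method steer a DEA projection.")
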