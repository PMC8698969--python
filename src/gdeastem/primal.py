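"""Multiplier-side (primal) GDEA model.

Maximises the efficiency score Δo over output weights u and input
weights v on the ε-bounded simplex:

    max Δo
    s.t.  Δo ≤ Σ_r u_r [α(y_ro − y_rj) + d̃_rj] + Σ_i v_i [α(x_ij − x_io) + d̃_ij]
          Σu + Σv = 1,  u_r ≥ ε,  v_i ≥ ε
          (CCR preset adds Σ_r u_r y_ro − Σ_i v_i x_io = 0)

The d̃ expansion uses the same deviation-matrix convention as the dual,
so the two problems form an exact LP dual pair and strong duality
Δ* = ω* − ε·Σ(slacks*) holds to solver precision.  Δ ≤ 0 always, since
the j = o constraint reads Δ ≤ 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from ._rows import coefficient_rows
from .config import GDEAConfig
from .dual import SolverError, _require_normalised
from .panel import DMUPanel


class EpsilonInfeasibleError(ValueError):
    """The weight simplex is empty: ε exceeds 1/(m+s)."""


@dataclass(frozen=True)
class PrimalSolution:
    focal: int
    label: str
    delta: float
    u: np.ndarray
    v: np.ndarray
    status: str
    is_alpha_efficient: bool


def solve_primal(panel_norm: DMUPanel, o: int, config: GDEAConfig) -> PrimalSolution:
    """Solve the multiplier model for focal unit ``o``."""
    _require_normalised(panel_norm)
    n, m, s = panel_norm.n, panel_norm.m, panel_norm.s
    C, A = coefficient_rows(panel_norm, o, config)
    # variables: delta (free), u (s), v (m)
    nv = 1 + s + m
    # constraint j: delta - C[:,j]·u - A[:,j]·v <= 0
    A_ub = np.zeros((n, nv))
    A_ub[:, 0] = 1.0
    A_ub[:, 1 : 1 + s] = -C.T
    A_ub[:, 1 + s :] = -A.T
    b_ub = np.zeros(n)
    rows = [np.concatenate([[0.0], np.ones(s + m)])]
    rhs = [1.0]
    if config.ccr_active:
        rows.append(np.concatenate([[0.0], panel_norm.outputs[o], -panel_norm.inputs[o]]))
        rhs.append(0.0)
    c = np.zeros(nv)
    c[0] = -1.0  # maximise delta
    bounds = [(None, None)] + [(config.epsilon, None)] * (s + m)
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=np.array(rows),
        b_eq=np.array(rhs),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": config.solver_tol,
                 "dual_feasibility_tolerance": config.solver_tol},
    )
    if res.status == 2:
        bound = config.epsilon_bound(m, s)
        raise EpsilonInfeasibleError(
            f"multiplier LP infeasible: epsilon={config.epsilon} exceeds the "
            f"1/(m+s) = {bound} bound for this panel"
        )
    if res.status != 0:
        raise SolverError(f"multiplier LP for unit {panel_norm.labels[o]!r}: {res.message}")
    delta = -float(res.fun)
    return PrimalSolution(
        focal=o,
        label=panel_norm.labels[o],
        delta=delta,
        u=res.x[1 : 1 + s].copy(),
        v=res.x[1 + s :].copy(),
        status="optimal",
        is_alpha_efficient=bool(abs(delta) <= config.tol_zero),
    )
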