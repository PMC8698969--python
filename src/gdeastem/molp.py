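"""Multi-objective restatement of the envelopment model for one focal unit.

The dual's s output rows become the objective vector

    f_r(λ) = Σ_j [α(y_ro − y_rj) + d̃_rj] λ_j + T·y_ro,   r = 1..s

to be minimised over the simplex, with the m input rows acting as
constraints ``g_i(λ) ≤ ω̄``.  The max-ordering scalarisation minimises an
auxiliary ω bounding every objective and input row, which recovers the
dual's optimal ω exactly (at ε = 0) — the bridge that lets an
interactive multi-objective procedure drive a DEA projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from ._rows import coefficient_rows
from .config import GDEAConfig
from .dual import SolverError, _require_normalised, solve_dual
from .normalization import column_norms
from .panel import DMUPanel


@dataclass(frozen=True)
class MOLPProblem:
    """Objective and input rows over the λ simplex for one focal unit.

    ``obj_rows`` is the s×n matrix C, ``in_rows`` the m×n matrix A;
    ``const_out``/``const_in`` carry the T·y_ro / −T·x_io terms (zero
    unless built from a CCR solution).  ``input_bound`` ω̄ is the
    right-hand side of the input rows during preference exploration
    (0 by default: iterates stay within the frontier-feasible region).
    ``out_divisors`` are the raw-scale column norms, kept so preference
    relaxations stated in raw output units can be mapped onto the
    objective scale.
    """

    focal: int
    labels: tuple[str, ...]
    obj_rows: np.ndarray      # (s, n)
    in_rows: np.ndarray       # (m, n)
    const_out: np.ndarray     # (s,)
    const_in: np.ndarray      # (m,)
    alpha: float
    input_bound: float = 0.0
    out_divisors: np.ndarray | None = None
    in_divisors: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.obj_rows.shape[1]

    @property
    def s(self) -> int:
        return self.obj_rows.shape[0]

    @property
    def m(self) -> int:
        return self.in_rows.shape[0]

    def objectives(self, lam: np.ndarray) -> np.ndarray:
        return self.obj_rows @ lam + self.const_out

    def input_values(self, lam: np.ndarray) -> np.ndarray:
        return self.in_rows @ lam + self.const_in

    def to_json(self) -> str:
        return json.dumps(
            {
                "focal": self.focal,
                "labels": list(self.labels),
                "obj_rows": self.obj_rows.tolist(),
                "in_rows": self.in_rows.tolist(),
                "const_out": self.const_out.tolist(),
                "const_in": self.const_in.tolist(),
                "alpha": self.alpha,
                "input_bound": self.input_bound,
            },
            indent=2,
        )


def to_molp(
    panel_norm: DMUPanel,
    o: int,
    config: GDEAConfig,
    input_bound: float = 0.0,
    raw_panel: DMUPanel | None = None,
) -> MOLPProblem:
    """Build the multi-objective program for focal unit ``o``.

    When the preset is CCR, T is held at the dual-optimal value (it is a
    model variable, not a preference lever).  Passing the matching raw
    panel records the normalisation divisors used for raw-scale
    relaxations.
    """
    _require_normalised(panel_norm)
    C, A = coefficient_rows(panel_norm, o, config)
    s, m = panel_norm.s, panel_norm.m
    const_out = np.zeros(s)
    const_in = np.zeros(m)
    if config.ccr_active:
        T = solve_dual(panel_norm, o, config).T
        const_out = T * panel_norm.outputs[o]
        const_in = -T * panel_norm.inputs[o]
    out_div = in_div = None
    if raw_panel is not None:
        in_div, out_div = column_norms(raw_panel)
    return MOLPProblem(
        focal=o,
        labels=panel_norm.labels,
        obj_rows=C,
        in_rows=A,
        const_out=const_out,
        const_in=const_in,
        alpha=config.alpha,
        input_bound=input_bound,
        out_divisors=out_div,
        in_divisors=in_div,
    )


def max_ordering_solve(molp: MOLPProblem) -> tuple[float, np.ndarray]:
    """Minimise the auxiliary ω bounding every objective and input row.

    Returns the optimal (ω, λ); ω equals the envelopment model's optimal
    ω for the same unit and convention (with the ε slack reward absent).
    """
    n, s, m = molp.n, molp.s, molp.m
    # variables: lam (n), omega (free)
    nv = n + 1
    A_ub = np.zeros((s + m, nv))
    A_ub[:s, :n] = molp.obj_rows
    A_ub[s:, :n] = molp.in_rows
    A_ub[:, n] = -1.0
    b_ub = np.concatenate([-molp.const_out, -molp.const_in])
    A_eq = np.zeros((1, nv))
    A_eq[0, :n] = 1.0
    c = np.zeros(nv)
    c[n] = 1.0
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
        bounds=[(0, None)] * n + [(None, None)], method="highs",
    )
    if res.status != 0:
        raise SolverError(f"max-ordering LP: {res.message}")
    return float(res.x[n]), res.x[:n].copy()


def induced_efficiency(molp: MOLPProblem, lam: np.ndarray) -> float:
    """Largest objective or input row value at λ.

    At the max-ordering optimum this equals ω; at λ = e_focal it is 0.
    Reported per iterate of the interactive loop as the unit's current
    efficiency surrogate.
    """
    lam = np.asarray(lam, dtype=float)
    return float(max(molp.objectives(lam).max(), molp.input_values(lam).max()))
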