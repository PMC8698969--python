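"""Envelopment-side (dual) GDEA model: efficiency, reference sets, targets.

For a focal unit o the dual minimises ``ω − ε(Σt^y + Σt^x)`` subject to

    Σ_j [α(y_ro − y_rj) + d̃_rj] λ_j − ω + t^y_r + T·y_ro = 0,   r = 1..s
    Σ_j [α(−x_io + x_ij) + d̃_ij] λ_j − ω + t^x_i − T·x_io = 0,  i = 1..m
    Σ_j λ_j = 1,   λ ≥ 0,  t ≥ 0,  T free (fixed at 0 unless CCR)

ω never exceeds zero (λ = e_o is feasible with objective 0); the unit is
α-efficient iff ω and every slack vanish at the optimum.  The support of
λ is the reference set, whose raw-scale convex combination is the
frontier target for an inefficient unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from ._rows import coefficient_rows
from .config import GDEAConfig
from .normalization import euclidean_normalize
from .panel import DMUPanel, NORMALISED, PanelError


class SolverError(RuntimeError):
    """LP solver failed or reported an unexpected status."""


@dataclass(frozen=True)
class DualSolution:
    """Optimal point of the envelopment model for one focal unit."""

    focal: int
    label: str
    omega: float
    lam: np.ndarray
    slacks_out: np.ndarray
    slacks_in: np.ndarray
    T: float
    objective: float
    status: str
    is_alpha_efficient: bool
    tol_zero: float = 1e-7

    @property
    def reference_set(self) -> list[int]:
        """Indices j with λ_j above the classification tolerance."""
        return [int(j) for j in np.flatnonzero(self.lam > self.tol_zero)]


@dataclass(frozen=True)
class ProjectionResult:
    """Raw-scale frontier target obtained from simplex weights λ."""

    ref_weights: dict[int, float]
    target_inputs: np.ndarray
    target_outputs: np.ndarray
    rounding: str = "none"


def _require_normalised(panel: DMUPanel) -> None:
    if panel.scale != NORMALISED:
        raise PanelError("expected a normalised-scale panel (run euclidean_normalize first)")


def solve_dual(panel_norm: DMUPanel, o: int, config: GDEAConfig) -> DualSolution:
    """Solve the envelopment model for focal unit ``o``."""
    _require_normalised(panel_norm)
    n, m, s = panel_norm.n, panel_norm.m, panel_norm.s
    C, A = coefficient_rows(panel_norm, o, config)
    ccr = config.ccr_active
    # variables: lam (n), omega (1, free), t^y (s), t^x (m), [T free]
    nv = n + 1 + s + m + (1 if ccr else 0)
    rows, rhs = [], []
    for r in range(s):
        row = np.zeros(nv)
        row[:n] = C[r]
        row[n] = -1.0
        row[n + 1 + r] = 1.0
        if ccr:
            row[-1] = panel_norm.outputs[o, r]
        rows.append(row)
        rhs.append(0.0)
    for i in range(m):
        row = np.zeros(nv)
        row[:n] = A[i]
        row[n] = -1.0
        row[n + 1 + s + i] = 1.0
        if ccr:
            row[-1] = -panel_norm.inputs[o, i]
        rows.append(row)
        rhs.append(0.0)
    row = np.zeros(nv)
    row[:n] = 1.0
    rows.append(row)
    rhs.append(1.0)

    c = np.zeros(nv)
    c[n] = 1.0
    c[n + 1 : n + 1 + s + m] = -config.epsilon
    bounds = [(0, None)] * n + [(None, None)] + [(0, None)] * (s + m)
    if ccr:
        bounds.append((None, None))
    res = linprog(
        c,
        A_eq=np.array(rows),
        b_eq=np.array(rhs),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": config.solver_tol,
                 "dual_feasibility_tolerance": config.solver_tol},
    )
    if res.status != 0:
        raise SolverError(
            f"envelopment LP for unit {panel_norm.labels[o]!r} ended with status "
            f"{res.status}: {res.message} (the model is feasible by construction; "
            "this signals a construction bug)"
        )
    x = res.x
    omega = float(x[n])
    slacks_out = x[n + 1 : n + 1 + s].copy()
    slacks_in = x[n + 1 + s : n + 1 + s + m].copy()
    tol = config.tol_zero
    efficient = abs(omega) <= tol and slacks_out.max(initial=0.0) <= tol and slacks_in.max(initial=0.0) <= tol
    return DualSolution(
        focal=o,
        label=panel_norm.labels[o],
        omega=omega,
        lam=x[:n].copy(),
        slacks_out=slacks_out,
        slacks_in=slacks_in,
        T=float(x[-1]) if ccr else 0.0,
        objective=float(res.fun),
        status="optimal",
        is_alpha_efficient=bool(efficient),
        tol_zero=tol,
    )


def evaluate_all(
    panel: DMUPanel, config: GDEAConfig, data_source: str = "normalize"
) -> list[DualSolution]:
    """Solve the envelopment model for every unit.

    ``data_source="normalize"`` Euclidean-normalises a raw panel first;
    ``"as_given"`` uses the panel verbatim (needed to run on an already
    normalised table as printed).
    """
    if data_source == "normalize":
        panel_norm = euclidean_normalize(panel)
    elif data_source == "as_given":
        panel_norm = panel if panel.scale == NORMALISED else panel.with_scale(NORMALISED)
    else:
        raise ValueError(f"unknown data_source {data_source!r}")
    return [solve_dual(panel_norm, o, config) for o in range(panel.n)]


def project_to_frontier(
    panel_raw: DMUPanel, lam: np.ndarray, rounding: str = "none", weight_tol: float = 1e-7
) -> ProjectionResult:
    """λ-weighted convex combination of the raw columns.

    ``rounding="nearest_integer"`` rounds targets half-up, matching how
    integer patient counts and charges are reported.
    """
    lam = np.asarray(lam, dtype=float)
    if lam.shape != (panel_raw.n,):
        raise ValueError("weight vector length must equal the number of units")
    if abs(lam.sum() - 1.0) > 1e-6 or lam.min() < -1e-9:
        raise ValueError("weights must lie on the simplex (nonnegative, summing to 1)")
    t_in = lam @ panel_raw.inputs
    t_out = lam @ panel_raw.outputs
    if rounding == "nearest_integer":
        t_in = np.floor(t_in + 0.5)
        t_out = np.floor(t_out + 0.5)
    elif rounding != "none":
        raise ValueError(f"unknown rounding {rounding!r}")
    ref = {int(j): float(lam[j]) for j in np.flatnonzero(lam > weight_tol)}
    return ProjectionResult(ref_weights=ref, target_inputs=t_in, target_outputs=t_out, rounding=rounding)


def classification_sweep(
    panel: DMUPanel,
    alphas: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3),
    config: GDEAConfig | None = None,
    data_source: str = "normalize",
) -> dict[float, list[bool]]:
    """Efficiency classification of every unit across α decades.

    The FDH/BCC presets only promise behaviour for "sufficiently"
    small/large α; this reports how the classification actually moves.
    """
    config = config or GDEAConfig()
    out = {}
    for a in alphas:
        sols = evaluate_all(panel, config.with_(alpha=a), data_source)
        out[a] = [s.is_alpha_efficient for s in sols]
    return out
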