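"""Independent reference implementations used only for validation.

These never feed the main pipeline; they exist so users (and the test
suite) can cross-check the GDEA classifications against a brute-force
dominance scan and the textbook input-oriented envelopment models.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from .dual import SolverError
from .panel import DMUPanel

_SLACK = 1e-12  # absorbs float noise in exact comparisons


def fdh_dominance_efficient(panel: DMUPanel) -> list[bool]:
    """Flag each unit efficient iff no other unit weakly dominates it.

    Unit j dominates unit k when every input of j is ≤ and every output
    of j is ≥ the corresponding value of k, with strict improvement in at
    least one coordinate.  O(n²(m+s)) pairwise scan; scale-free under
    positive column scaling, so raw or normalised panels both work.
    """
    X, Y = panel.inputs, panel.outputs
    n = panel.n
    flags = [True] * n
    for k in range(n):
        for j in range(n):
            if j == k:
                continue
            weakly = np.all(X[j] <= X[k] + _SLACK) and np.all(Y[j] >= Y[k] - _SLACK)
            strict = np.any(X[j] < X[k] - _SLACK) or np.any(Y[j] > Y[k] + _SLACK)
            if weakly and strict:
                flags[k] = False
                break
    return flags


def envelopment_reference(panel: DMUPanel, o: int, model: str = "CCR") -> float:
    """Input-oriented radial efficiency θ ∈ (0, 1] of unit ``o``.

    min θ s.t. Xᵀλ ≤ θ·x_o, Yᵀλ ≥ y_o, λ ≥ 0 (CCR), plus Σλ = 1 for BCC.
    """
    model = model.upper()
    if model not in ("CCR", "BCC"):
        raise ValueError(f"unknown model {model!r}")
    X, Y = panel.inputs, panel.outputs
    n, m, s = panel.n, panel.m, panel.s
    if np.any(X[o] <= 0):
        raise ValueError("radial input orientation needs strictly positive inputs for the focal unit")
    # variables: lam (n), theta
    A_ub = np.zeros((m + s, n + 1))
    A_ub[:m, :n] = X.T
    A_ub[:m, n] = -X[o]
    A_ub[m:, :n] = -Y.T
    b_ub = np.concatenate([np.zeros(m), -Y[o]])
    A_eq = b_eq = None
    if model == "BCC":
        A_eq = np.zeros((1, n + 1))
        A_eq[0, :n] = 1.0
        b_eq = [1.0]
    c = np.zeros(n + 1)
    c[n] = 1.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * (n + 1), method="highs")
    if res.status != 0:
        raise SolverError(f"envelopment reference LP: {res.message}")
    return float(res.x[n])
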