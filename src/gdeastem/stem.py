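"""Interactive STEM (step method) loop over the focal unit's MOLP.

STEM minimises the weighted Tchebychev distance to the ideal point of
the s objectives, then lets the decision-maker (DM) trade off: in each
round the DM either accepts the iterate, or relaxes some objectives by
stated amounts Δf to make room for the others.  Relaxed objectives are
bound above by their previous value plus Δf and leave the Tchebychev
block (their weight becomes zero); maintained objectives may never
worsen.  The loop ends at the most preferred solution (MPS).

The published statement of the method is in maximisation form; the
GDEA-derived objectives here are minimised, so every inequality is
mirrored (ideal = per-objective minimum, "relax" = allow an increase).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.optimize import linprog

from .dual import ProjectionResult, SolverError, project_to_frontier
from .molp import MOLPProblem, induced_efficiency
from .panel import DMUPanel

OBJECTIVE_SCALE = "objective"
RAW_OUTPUT_SCALE = "raw_output"


class StemInfeasibleError(RuntimeError):
    """The relaxation amounts admit no feasible iterate; enlarge Δf."""


class PreferenceScriptError(ValueError):
    """Malformed preference script."""


@dataclass(frozen=True)
class Relaxation:
    """One DM concession: let objective ``objective`` (0-based) worsen by
    ``delta`` on the stated scale."""

    objective: int
    delta: float
    scale: str = OBJECTIVE_SCALE

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("relaxation amount must be nonnegative")
        if self.scale not in (OBJECTIVE_SCALE, RAW_OUTPUT_SCALE):
            raise ValueError(f"unknown relaxation scale {self.scale!r}")


@dataclass(frozen=True)
class PreferenceDirective:
    """DM response to an iterate: accept it, or adjust via relaxations."""

    action: str  # "accept" | "adjust"
    relax: tuple[Relaxation, ...] = ()
    improve: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.action not in ("accept", "adjust"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "accept" and (self.relax or self.improve):
            raise ValueError("an accept directive carries no relax/improve lists")
        relaxed = {r.objective for r in self.relax}
        if relaxed & set(self.improve):
            raise ValueError("relax and improve lists must be disjoint")

    @classmethod
    def accept(cls) -> "PreferenceDirective":
        return cls(action="accept")


@dataclass(frozen=True)
class PayoffTable:
    """Per-objective optima over the feasible set (minimisation form).

    ``payoff[k, r]`` is objective r evaluated at the minimiser of
    objective k; ``ideal`` is its diagonal, ``nadir_est`` the column-wise
    worst (maximum).
    """

    ideal: np.ndarray
    payoff: np.ndarray
    argmins: np.ndarray  # (s, n) minimising λ per objective


@dataclass(frozen=True)
class STEMState:
    """One iterate of the loop, with append-only relaxation history."""

    iteration: int
    lam: np.ndarray
    f: np.ndarray
    weights: np.ndarray
    tcheb: float
    relaxed_sets: tuple[frozenset[int], ...] = ()
    relaxations: tuple[tuple[tuple[int, float], ...], ...] = ()
    accepted: bool = False
    induced: float = float("nan")

    @property
    def ever_relaxed(self) -> frozenset[int]:
        out: set[int] = set()
        for js in self.relaxed_sets:
            out |= js
        return frozenset(out)


def _feasible_rows(molp: MOLPProblem) -> tuple[np.ndarray, np.ndarray]:
    """Input-row constraints A λ ≤ ω̄ − const_in defining Ω_o."""
    return molp.in_rows, molp.input_bound - molp.const_in


def _solve(c, A_ub, b_ub, A_eq, b_eq, bounds, what: str):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 2:
        raise StemInfeasibleError(
            f"{what} infeasible: the active bounds leave no feasible point; "
            "enlarge the relaxation amounts Δf or the input bound"
        )
    if res.status != 0:
        raise SolverError(f"{what}: {res.message}")
    return res


def payoff_table(molp: MOLPProblem) -> PayoffTable:
    """Solve the s single-objective LPs over Ω_o and tabulate them."""
    n, s = molp.n, molp.s
    G, h = _feasible_rows(molp)
    A_eq = np.ones((1, n))
    payoff = np.zeros((s, s))
    argmins = np.zeros((s, n))
    for k in range(s):
        res = _solve(molp.obj_rows[k], G, h, A_eq, [1.0], [(0, None)] * n,
                     f"payoff LP for objective {k + 1}")
        argmins[k] = res.x
        payoff[k] = molp.objectives(res.x)
    return PayoffTable(ideal=np.diag(payoff).copy(), payoff=payoff, argmins=argmins)


def stem_weights(payoff: PayoffTable, floor: float = 1e-9) -> np.ndarray:
    """Normalised Tchebychev weights from the payoff table.

    ``π_i = (nadir_i − ideal_i) / max(|nadir_i|, floor)`` then
    ``w = π / Σπ``; uniform if every range is zero.
    """
    nadir = payoff.payoff.max(axis=0)
    pi = (nadir - payoff.ideal) / np.maximum(np.abs(nadir), floor)
    total = pi.sum()
    if total <= 0:
        return np.full(payoff.ideal.shape, 1.0 / payoff.ideal.size)
    return pi / total


def _objective_scale_delta(molp: MOLPProblem, relax: Relaxation) -> float:
    if relax.scale == OBJECTIVE_SCALE:
        return relax.delta
    if molp.out_divisors is None:
        raise ValueError(
            "raw_output-scale relaxation needs the raw panel's column norms; "
            "build the MOLP with raw_panel=..."
        )
    return molp.alpha * relax.delta / float(molp.out_divisors[relax.objective])


def stem_step(
    molp: MOLPProblem,
    payoff: PayoffTable,
    state: STEMState | None = None,
    directive: PreferenceDirective | None = None,
) -> STEMState:
    """Compute the next Tchebychev iterate.

    The first call (``state=None``) takes no directive and minimises the
    weighted Tchebychev distance to the ideal over Ω_o.  Subsequent calls
    apply the DM's relaxations: relaxed objectives may worsen by at most
    Δf relative to the previous iterate, all others may not worsen, and
    the Tchebychev block is restricted to never-relaxed objectives with
    their weights renormalised.
    """
    n, s = molp.n, molp.s
    G, h = _feasible_rows(molp)
    A_eq = np.ones((1, n + 1))
    A_eq[0, n] = 0.0
    base_w = stem_weights(payoff)

    if state is None:
        active = [i for i in range(s) if base_w[i] > 0] or list(range(s))
        weights = base_w
        relaxed_sets: tuple[frozenset[int], ...] = ()
        relaxations: tuple[tuple[tuple[int, float], ...], ...] = ()
        extra_rows: list[np.ndarray] = []
        extra_rhs: list[float] = []
        iteration = 1
    else:
        if directive is None or directive.action != "adjust":
            raise ValueError("subsequent steps need an adjust directive")
        deltas = {r.objective: _objective_scale_delta(molp, r) for r in directive.relax}
        for k in deltas:
            if not 0 <= k < s:
                raise ValueError(f"relaxed objective index {k} out of range")
        ever = set(state.ever_relaxed) | set(deltas)
        active = [i for i in range(s) if i not in ever]
        w = base_w.copy()
        w[list(ever)] = 0.0
        if w.sum() > 0:
            w = w / w.sum()
        elif active:
            w[active] = 1.0 / len(active)
        weights = w
        extra_rows, extra_rhs = [], []
        for k in range(s):
            row = np.zeros(n + 1)
            row[:n] = molp.obj_rows[k]
            bound = float(state.f[k] - molp.const_out[k])
            if k in deltas:
                bound += deltas[k]
            extra_rows.append(row)
            extra_rhs.append(bound)
        relaxed_sets = state.relaxed_sets + (frozenset(deltas),)
        relaxations = state.relaxations + (tuple(sorted(deltas.items())),)
        iteration = state.iteration + 1

    # variables: lam (n), tcheb (>= 0)
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    for i in active:
        row = np.zeros(n + 1)
        row[:n] = weights[i] * molp.obj_rows[i]
        row[n] = -1.0
        rows.append(row)
        rhs.append(float(weights[i] * (payoff.ideal[i] - molp.const_out[i])))
    for g_row, g_rhs in zip(G, h):
        row = np.zeros(n + 1)
        row[:n] = g_row
        rows.append(row)
        rhs.append(float(g_rhs))
    rows.extend(extra_rows)
    rhs.extend(extra_rhs)
    c = np.zeros(n + 1)
    c[n] = 1.0
    res = _solve(c, np.array(rows), np.array(rhs), A_eq, [1.0],
                 [(0, None)] * n + [(0, None)], f"STEM step {iteration}")
    lam = res.x[:n].copy()
    return STEMState(
        iteration=iteration,
        lam=lam,
        f=molp.objectives(lam),
        weights=weights,
        tcheb=float(res.x[n]),
        relaxed_sets=relaxed_sets,
        relaxations=relaxations,
        induced=induced_efficiency(molp, lam),
    )


PreferenceOracle = Callable[[STEMState, ProjectionResult | None], PreferenceDirective]


class ScriptedOracle:
    """Replays a fixed list of directives, then accepts."""

    def __init__(self, directives: Sequence[PreferenceDirective]):
        self._queue = list(directives)

    def __call__(self, state: STEMState, projection: ProjectionResult | None) -> PreferenceDirective:
        if not self._queue:
            return PreferenceDirective.accept()
        return self._queue.pop(0)


def run_stem(
    molp: MOLPProblem,
    oracle: PreferenceOracle,
    max_iter: int = 20,
    raw_panel: DMUPanel | None = None,
) -> tuple[np.ndarray, list[STEMState]]:
    """Drive the loop until the oracle accepts or ``max_iter`` is reached.

    The oracle sees each iterate (and its raw-scale projection when a raw
    panel is supplied) and answers with a directive.  Returns the
    accepted λ — the MPS — and the full iterate history; if the budget
    runs out the last iterate is returned unaccepted.
    """
    payoff = payoff_table(molp)
    history: list[STEMState] = []
    state = stem_step(molp, payoff)
    for _ in range(max_iter):
        projection = (
            project_to_frontier(raw_panel, state.lam, rounding="nearest_integer")
            if raw_panel is not None
            else None
        )
        directive = oracle(state, projection)
        if directive.action == "accept":
            state = dataclasses.replace(state, accepted=True)
            history.append(state)
            return state.lam, history
        history.append(state)
        state = stem_step(molp, payoff, state, directive)
    history.append(state)
    return state.lam, history


def load_preference_script(path: str | Path) -> list[PreferenceDirective]:
    """Parse an ordered YAML/JSON list of directives.

    Each entry is the string ``accept`` or a mapping
    ``{relax: [{objective: k, delta: d, scale: raw_output|objective}], improve: [..]}``
    with 1-based objective indices.
    """
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise PreferenceScriptError(f"{path}: {e}") from e
    if not isinstance(doc, list):
        raise PreferenceScriptError(f"{path}: expected a top-level list of directives")
    out: list[PreferenceDirective] = []
    for ln, entry in enumerate(doc, start=1):
        if entry == "accept" or entry == {"accept": True}:
            out.append(PreferenceDirective.accept())
            continue
        if not isinstance(entry, dict):
            raise PreferenceScriptError(f"{path}: directive {ln} is not 'accept' or a mapping")
        try:
            relax = tuple(
                Relaxation(
                    objective=int(r["objective"]) - 1,
                    delta=float(r["delta"]),
                    scale=str(r.get("scale", OBJECTIVE_SCALE)),
                )
                for r in entry.get("relax", [])
            )
            improve = tuple(int(k) - 1 for k in entry.get("improve", []))
            out.append(PreferenceDirective(action="adjust", relax=relax, improve=improve))
        except (KeyError, TypeError, ValueError) as e:
            raise PreferenceScriptError(f"{path}: directive {ln}: {e}") from e
    return out
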