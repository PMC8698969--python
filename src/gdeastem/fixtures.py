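"""Embedded case-study data and a seeded synthetic-panel generator.

The case study is a 2020 panel of 14 hospitals providing stroke care:
two inputs — average length of stay (ALOS, hours) and average
occupational/physical-therapy charges (tens of dollars) — and three
outputs — average severe, semi-severe and mild patients per provider.

Both the raw table and its published normalised counterpart are embedded
verbatim.  The normalised table's output columns are *not* the Euclidean
normalisation of the raw outputs (a documented inconsistency of the
source data); the printed normalised table is therefore the canonical
input whenever published efficiency values or worked coefficients are
being reproduced, while :func:`gdeastem.normalization.euclidean_normalize`
is what one would run on fresh raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oracles import fdh_dominance_efficient
from .panel import DMUPanel, NORMALISED, RAW

_IN_NAMES = ("alos", "otpt")
_OUT_NAMES = ("severe", "semisevere", "mild")

# rows: hospitals 1..14; columns: ALOS, OT/PT | severe, semi-severe, mild
_RAW_INPUTS = [
    (168, 217), (187, 177), (115, 278), (151, 266), (105, 219), (172, 291),
    (124, 203), (184, 188), (273, 131), (167, 119), (175, 249), (177, 167),
    (154, 249), (206, 257),
]
_RAW_OUTPUTS = [
    (242, 198, 291), (185, 243, 176), (103, 247, 133), (170, 129, 133),
    (115, 222, 171), (155, 122, 340), (103, 197, 176), (207, 236, 201),
    (298, 325, 240), (141, 115, 214), (201, 355, 185), (281, 272, 195),
    (210, 357, 451), (330, 198, 291),
]
_NORM_INPUTS = [
    (0.26, 0.2624), (0.2885, 0.2138), (0.1771, 0.3356), (0.2333, 0.3216),
    (0.1622, 0.2644), (0.2648, 0.3511), (0.192, 0.2458), (0.2844, 0.2275),
    (0.4205, 0.1582), (0.2582, 0.1439), (0.2702, 0.3003), (0.2735, 0.2025),
    (0.2381, 0.3015), (0.318, 0.3101),
]
_NORM_OUTPUTS = [
    (0.3216, 0.217, 0.3111), (0.1942, 0.2671, 0.238), (0.1478, 0.2709, 0.1336),
    (0.1475, 0.1413, 0.2189), (0.1895, 0.2439, 0.148), (0.376, 0.1337, 0.1996),
    (0.1949, 0.2165, 0.1325), (0.2219, 0.2594, 0.2665), (0.2657, 0.3576, 0.3829),
    (0.2372, 0.1267, 0.1819), (0.2049, 0.3897, 0.2585), (0.2157, 0.2983, 0.3612),
    (0.4986, 0.3921, 0.2709), (0.2945, 0.2412, 0.4245),
]


def hospital_panel() -> DMUPanel:
    """The raw 14-hospital panel (2 inputs, 3 outputs), labels "1".."14"."""
    return DMUPanel(
        labels=tuple(str(i + 1) for i in range(14)),
        inputs=np.array(_RAW_INPUTS, dtype=float),
        outputs=np.array(_RAW_OUTPUTS, dtype=float),
        scale=RAW,
        input_names=_IN_NAMES,
        output_names=_OUT_NAMES,
    )


def hospital_panel_normalized() -> DMUPanel:
    """The published normalised hospital panel, embedded digit-for-digit."""
    return DMUPanel(
        labels=tuple(str(i + 1) for i in range(14)),
        inputs=np.array(_NORM_INPUTS, dtype=float),
        outputs=np.array(_NORM_OUTPUTS, dtype=float),
        scale=NORMALISED,
        input_names=_IN_NAMES,
        output_names=_OUT_NAMES,
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic panel shaped like the hospital case study.

    Frontier units are pairwise non-dominated; each planted inefficient
    unit is a frontier unit with inputs scaled up by a multiplier drawn
    from (1, u_max] and outputs scaled down by its reciprocal, so it is
    strictly dominated by its recorded parent.
    """

    n_frontier: int = 6
    n_dominated: int = 4
    m: int = 2
    s: int = 3
    input_low: float = 100.0
    input_high: float = 300.0
    frontier_form: str = "cobb_douglas"  # or "random_nondominated"
    u_max: float = 1.5
    seed: int = 0
    max_retries: int = 2000

    def __post_init__(self) -> None:
        if self.n_frontier < 1 or self.n_dominated < 0:
            raise ValueError("need at least one frontier unit and nonnegative dominated count")
        if self.u_max <= 1:
            raise ValueError("u_max must exceed 1")
        if self.frontier_form not in ("cobb_douglas", "random_nondominated"):
            raise ValueError(f"unknown frontier_form {self.frontier_form!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a synthetic panel."""

    dominated: tuple[bool, ...]
    parent: dict[int, int]  # dominated index -> frontier parent index
    seed: int


def _candidate(rng: np.random.Generator, spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    x = np.exp(rng.uniform(np.log(spec.input_low), np.log(spec.input_high), spec.m))
    if spec.frontier_form == "cobb_douglas":
        # decreasing-returns technology with per-output exponents and a
        # mild idiosyncratic tilt, scaled to the input magnitude
        expo = rng.uniform(0.2, 0.8, (spec.s, spec.m))
        expo /= expo.sum(axis=1, keepdims=True)
        tilt = rng.uniform(0.8, 1.25, spec.s)
        y = tilt * np.prod(x[None, :] ** expo, axis=1)
    else:
        y = rng.uniform(spec.input_low, spec.input_high, spec.s)
    return x, y


def generate_synthetic(spec: SyntheticSpec) -> tuple[DMUPanel, GroundTruth]:
    """Draw a reproducible synthetic panel with recorded ground truth."""
    rng = np.random.default_rng(spec.seed)
    frontier_x: list[np.ndarray] = []
    frontier_y: list[np.ndarray] = []
    tries = 0
    while len(frontier_x) < spec.n_frontier:
        if tries > spec.max_retries:
            raise RuntimeError(
                "rejection sampling exhausted its retry budget; widen the "
                "input_low/input_high range or reduce n_frontier"
            )
        tries += 1
        x, y = _candidate(rng, spec)
        ok = True
        for xf, yf in zip(frontier_x, frontier_y):
            dominates = np.all(xf <= x) and np.all(yf >= y)
            dominated = np.all(x <= xf) and np.all(y >= yf)
            if dominates or dominated:
                ok = False
                break
        if ok:
            frontier_x.append(x)
            frontier_y.append(y)
    X = list(frontier_x)
    Y = list(frontier_y)
    parent: dict[int, int] = {}
    for k in range(spec.n_dominated):
        p = int(rng.integers(spec.n_frontier))
        u = rng.uniform(1.05, spec.u_max)
        idx = spec.n_frontier + k
        parent[idx] = p
        X.append(frontier_x[p] * u)
        Y.append(frontier_y[p] / u)
    panel = DMUPanel(
        labels=tuple(str(i + 1) for i in range(len(X))),
        inputs=np.array(X),
        outputs=np.array(Y),
        scale=RAW,
    )
    flags = tuple([False] * spec.n_frontier + [True] * spec.n_dominated)
    truth = GroundTruth(dominated=flags, parent=parent, seed=spec.seed)
    # by-construction guarantee, checked against the independent scan
    eff = fdh_dominance_efficient(panel)
    assert all(not eff[i] for i in parent), "planted unit escaped dominance"
    return panel, truth
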