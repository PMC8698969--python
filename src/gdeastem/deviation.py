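"""Deviation quantities d̃ relating a focal unit to its peers.

For a focal unit ``o`` on the normalised scale, the raw materials are the
output differences ``y_ro − y_rj`` (s per peer) and the input differences
``x_ij − x_io`` (m per peer).  The GDEA primal keeps, per peer, a selected
maximum; the dual and the derived multi-objective program arrange selected
maxima into s×n / m×n matrices.  Three arrangements are supported:

``column_max``
    In each peer column, keep the largest output difference at its own
    position and zero the rest; same, separately, for input differences.
``cumulative_max``
    Entry (r, j) is the running maximum of the first r output differences
    for peer j; entry (i, j) the running maximum of the first i input
    differences.  This is the arrangement consistent with the worked
    hospital example's printed coefficients.
``union_max``
    In each peer column, keep only the single largest difference over
    outputs and inputs jointly, at its own position.  This mirrors the
    primal's selection rule exactly; under it, small-α efficiency
    coincides with free-disposal-hull non-dominance.
``zero``
    All deviation entries are zero, leaving the purely additive model
    (the unit-scale large-α limit).  This is the arrangement that
    reproduces the published hospital efficiency table.

Tie-breaking in every maximum is deterministic: outputs before inputs,
then lowest index.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .panel import DMUPanel


class Convention(str, enum.Enum):
    """Arrangement rule for the deviation matrices."""

    COLUMN_MAX = "column_max"
    CUMULATIVE_MAX = "cumulative_max"
    UNION_MAX = "union_max"
    ZERO = "zero"


@dataclass(frozen=True)
class MaxDeviationTag:
    """The single selected difference for one peer, per the primal rule.

    ``kind`` is ``"output"`` or ``"input"``; ``index`` is the 0-based
    output index p or input index q whose weight the primal applies.
    """

    j: int
    kind: str
    index: int
    value: float


@dataclass(frozen=True)
class DeviationMatrices:
    """d̃ arranged as an s×n output block and an m×n input block."""

    convention: Convention
    out_dev: np.ndarray  # (s, n)
    in_dev: np.ndarray   # (m, n)
    focal: int


def _differences(panel: DMUPanel, o: int) -> tuple[np.ndarray, np.ndarray]:
    out_diff = (panel.outputs[o][None, :] - panel.outputs).T  # (s, n): y_ro - y_rj
    in_diff = (panel.inputs - panel.inputs[o][None, :]).T     # (m, n): x_ij - x_io
    return out_diff, in_diff


def select_max_deviation(panel_norm: DMUPanel, o: int) -> list[MaxDeviationTag]:
    """Select, per peer, the largest difference over outputs and inputs jointly.

    Ties are broken outputs-first, then lowest index.  The focal unit's
    own tag has value 0.
    """
    out_diff, in_diff = _differences(panel_norm, o)
    s = panel_norm.s
    stacked = np.vstack([out_diff, in_diff])  # outputs first => argmax tie rule
    tags: list[MaxDeviationTag] = []
    for j in range(panel_norm.n):
        if j == o:
            tags.append(MaxDeviationTag(j=j, kind="output", index=0, value=0.0))
            continue
        k = int(np.argmax(stacked[:, j]))
        if k < s:
            tags.append(MaxDeviationTag(j=j, kind="output", index=k, value=float(stacked[k, j])))
        else:
            tags.append(MaxDeviationTag(j=j, kind="input", index=k - s, value=float(stacked[k, j])))
    return tags


def build_deviation_matrices(
    panel_norm: DMUPanel, o: int, convention: Convention | str = Convention.COLUMN_MAX
) -> DeviationMatrices:
    """Arrange the d̃ quantities for focal unit ``o`` under a convention."""
    convention = Convention(convention)
    out_diff, in_diff = _differences(panel_norm, o)
    s, n = out_diff.shape
    m = in_diff.shape[0]
    out_dev = np.zeros((s, n))
    in_dev = np.zeros((m, n))
    if convention is Convention.ZERO:
        pass
    elif convention is Convention.COLUMN_MAX:
        for j in range(n):
            if j == o:
                continue
            r = int(np.argmax(out_diff[:, j]))  # first max => lowest index on ties
            out_dev[r, j] = out_diff[r, j]
            i = int(np.argmax(in_diff[:, j]))
            in_dev[i, j] = in_diff[i, j]
    elif convention is Convention.UNION_MAX:
        for tag in select_max_deviation(panel_norm, o):
            if tag.j == o:
                continue
            if tag.kind == "output":
                out_dev[tag.index, tag.j] = tag.value
            else:
                in_dev[tag.index, tag.j] = tag.value
    elif convention is Convention.CUMULATIVE_MAX:
        out_dev = np.maximum.accumulate(out_diff, axis=0)
        in_dev = np.maximum.accumulate(in_diff, axis=0)
        out_dev[:, o] = 0.0
        in_dev[:, o] = 0.0
    else:  # pragma: no cover
        raise ValueError(f"unknown convention {convention}")
    return DeviationMatrices(convention=convention, out_dev=out_dev, in_dev=in_dev, focal=o)
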