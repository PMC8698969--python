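"""Decision-making-unit panels and CSV round-tripping.

A panel holds ``n`` decision-making units (DMUs), each consuming ``m``
nonnegative inputs to produce ``s`` nonnegative outputs.  Columns in a
panel CSV are declared by prefix: ``in_<name>`` for inputs, ``out_<name>``
for outputs, plus one label column (``dmu`` by default, else the first
unprefixed column).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

RAW = "raw"
NORMALISED = "normalised"


class PanelError(ValueError):
    """Raised for malformed panel data or files."""


@dataclass(frozen=True)
class DMUPanel:
    """Immutable container for a DMU panel.

    Parameters
    ----------
    labels : sequence of str
        Unique, non-empty unit identifiers (reported 1-based elsewhere).
    inputs : (n, m) array
        Nonnegative input quantities ``x_ij``.
    outputs : (n, s) array
        Nonnegative output quantities ``y_rj``.
    scale : str
        ``"raw"`` or ``"normalised"``.
    input_names, output_names : sequence of str, optional
        Column names (defaults ``x1..xm`` / ``y1..ys``).
    """

    labels: tuple[str, ...]
    inputs: np.ndarray
    outputs: np.ndarray
    scale: str = RAW
    input_names: tuple[str, ...] = field(default=())
    output_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        outputs = np.atleast_2d(np.asarray(self.outputs, dtype=float))
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "outputs", outputs)
        object.__setattr__(self, "labels", labels)
        n = len(labels)
        if n < 1:
            raise PanelError("panel needs at least one unit")
        if inputs.shape[0] != n or outputs.shape[0] != n:
            raise PanelError(
                f"matrix shapes {inputs.shape}/{outputs.shape} inconsistent with {n} labels"
            )
        if inputs.shape[1] < 1 or outputs.shape[1] < 1:
            raise PanelError("panel needs at least one input and one output column")
        if any(l == "" for l in labels):
            raise PanelError("empty unit label")
        if len(set(labels)) != n:
            raise PanelError("unit labels must be unique")
        for name, mat in (("input", inputs), ("output", outputs)):
            bad = ~np.isfinite(mat)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise PanelError(f"non-finite {name} at unit {labels[r]!r}, column {c + 1}")
            neg = mat < 0
            if neg.any():
                r, c = np.argwhere(neg)[0]
                raise PanelError(f"negative {name} at unit {labels[r]!r}, column {c + 1}")
        if self.scale not in (RAW, NORMALISED):
            raise PanelError(f"unknown scale tag {self.scale!r}")
        if not self.input_names:
            object.__setattr__(
                self, "input_names", tuple(f"x{i + 1}" for i in range(inputs.shape[1]))
            )
        if not self.output_names:
            object.__setattr__(
                self, "output_names", tuple(f"y{r + 1}" for r in range(outputs.shape[1]))
            )
        if len(self.input_names) != inputs.shape[1] or len(self.output_names) != outputs.shape[1]:
            raise PanelError("column-name lengths inconsistent with matrices")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def m(self) -> int:
        return self.inputs.shape[1]

    @property
    def s(self) -> int:
        return self.outputs.shape[1]

    def unit_index(self, label: str | int) -> int:
        """0-based index of a unit given its label (or a 1-based position)."""
        label = str(label)
        if label in self.labels:
            return self.labels.index(label)
        raise PanelError(f"unknown unit label {label!r}")

    def with_scale(self, scale: str) -> "DMUPanel":
        return replace(self, scale=scale)

    def to_json(self) -> str:
        """JSON export, mainly for embedding small fixture panels."""
        import json

        return json.dumps(
            {
                "labels": list(self.labels),
                "inputs": self.inputs.tolist(),
                "outputs": self.outputs.tolist(),
                "scale": self.scale,
                "input_names": list(self.input_names),
                "output_names": list(self.output_names),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DMUPanel":
        import json

        doc = json.loads(text)
        return cls(
            labels=tuple(doc["labels"]),
            inputs=np.array(doc["inputs"], dtype=float),
            outputs=np.array(doc["outputs"], dtype=float),
            scale=doc.get("scale", RAW),
            input_names=tuple(doc.get("input_names", ())),
            output_names=tuple(doc.get("output_names", ())),
        )


def focal_index(panel: DMUPanel, unit: str | int) -> int:
    """Resolve a user-facing unit reference to a 0-based focal index."""
    return panel.unit_index(unit)


def read_panel(
    path: str | Path,
    label_col: str = "dmu",
    input_cols: Sequence[str] | None = None,
    output_cols: Sequence[str] | None = None,
    scale: str = RAW,
) -> DMUPanel:
    """Read a panel CSV.

    Inputs and outputs are recognised by the ``in_``/``out_`` prefix
    convention unless explicit column lists are given.
    """
    df = pd.read_csv(path)
    if label_col in df.columns:
        labels = df[label_col].astype(str).tolist()
    else:
        labels = df.iloc[:, 0].astype(str).tolist()
        label_col = df.columns[0]
    if input_cols is None:
        input_cols = [c for c in df.columns if c.startswith("in_")]
    if output_cols is None:
        output_cols = [c for c in df.columns if c.startswith("out_")]
    if not input_cols:
        raise PanelError(f"{path}: no input columns (expected 'in_<name>' headers)")
    if not output_cols:
        raise PanelError(f"{path}: no output columns (expected 'out_<name>' headers)")
    for cols in (input_cols, output_cols):
        for c in cols:
            if c not in df.columns:
                raise PanelError(f"{path}: declared column {c!r} missing")
            vals = pd.to_numeric(df[c], errors="coerce")
            if vals.isna().any():
                row = int(vals.isna().idxmax())
                raise PanelError(f"{path}: missing or non-numeric value at row {row + 1}, column {c!r}")
    return DMUPanel(
        labels=tuple(labels),
        inputs=df[list(input_cols)].to_numpy(dtype=float),
        outputs=df[list(output_cols)].to_numpy(dtype=float),
        scale=scale,
        input_names=tuple(c.removeprefix("in_") for c in input_cols),
        output_names=tuple(c.removeprefix("out_") for c in output_cols),
    )


def write_panel(panel: DMUPanel, path: str | Path) -> None:
    """Write a panel CSV that round-trips through :func:`read_panel`.

    Values are written with 12 significant digits.
    """
    df = pd.DataFrame({"dmu": panel.labels})
    for i, name in enumerate(panel.input_names):
        df[f"in_{name}"] = panel.inputs[:, i]
    for r, name in enumerate(panel.output_names):
        df[f"out_{name}"] = panel.outputs[:, r]
    df.to_csv(path, index=False, float_format="%.12g")
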