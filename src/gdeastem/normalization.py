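"""Column-wise Euclidean-norm normalisation of a raw panel.

Each input and output column is divided by its Euclidean norm over all
``n`` units, mapping every entry into ``[0, 1]`` while preserving
within-column ratios.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .panel import DMUPanel, NORMALISED, PanelError, RAW


def column_norms(panel: DMUPanel) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean norms of the input and output columns.

    These are the divisors applied by :func:`euclidean_normalize`; the
    STEM loop reuses them to convert raw-scale relaxations onto the
    normalised objective scale.
    """
    return (
        np.linalg.norm(panel.inputs, axis=0),
        np.linalg.norm(panel.outputs, axis=0),
    )


def euclidean_normalize(panel: DMUPanel) -> DMUPanel:
    """Divide every column by its Euclidean norm.

    Raises
    ------
    PanelError
        If the panel is already normalised or a column is all zero.
    """
    if panel.scale != RAW:
        raise PanelError("euclidean_normalize expects a raw-scale panel")
    in_norms, out_norms = column_norms(panel)
    for norms, names in ((in_norms, panel.input_names), (out_norms, panel.output_names)):
        if np.any(norms == 0):
            bad = names[int(np.argmin(norms))]
            raise PanelError(f"column {bad!r} is all zero; Euclidean norm undefined")
    return replace(
        panel,
        inputs=panel.inputs / in_norms,
        outputs=panel.outputs / out_norms,
        scale=NORMALISED,
    )
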