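"""Shared coefficient rows for the dual, primal and MOLP builders."""

from __future__ import annotations

import numpy as np

from .config import GDEAConfig
from .deviation import _differences, build_deviation_matrices
from .panel import DMUPanel


def coefficient_rows(
    panel_norm: DMUPanel, o: int, config: GDEAConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Return (C, A): the s×n output rows α(y_ro−y_rj)+d̃_rj and the
    m×n input rows α(−x_io+x_ij)+d̃_ij, excluding any T terms."""
    out_diff, in_diff = _differences(panel_norm, o)
    dev = build_deviation_matrices(panel_norm, o, config.dtilde_convention)
    C = config.alpha * out_diff + dev.out_dev
    A = config.alpha * in_diff + dev.in_dev
    return C, A
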