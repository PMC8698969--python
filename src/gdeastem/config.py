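"""Model configuration for the generalised DEA family.

The scale parameter α interpolates between the free-disposal-hull model
(small α), the variable-returns BCC model (large α), and the
constant-returns CCR model (large α plus the active ratio constraint,
realised through the free dual variable T).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .deviation import Convention

FDH = "fdh"
BCC = "bcc"
CCR = "ccr"

#: α used when a preset asks for "sufficiently large".
LARGE_ALPHA = 1e3


@dataclass(frozen=True)
class GDEAConfig:
    """Parameters shared by the GDEA primal, dual and derived programs.

    Attributes
    ----------
    alpha : float
        Positive scale parameter α.
    epsilon : float
        Non-Archimedean lower bound on the multiplier weights; must not
        exceed ``1/(m+s)`` for the panel it is applied to.
    preset : str
        ``"fdh"``, ``"bcc"`` or ``"ccr"``; CCR activates the free ratio
        variable T.
    dtilde_convention : Convention
        Arrangement of the deviation quantities (see :mod:`.deviation`).
    tol_zero : float
        Classification tolerance on |ω| and on each slack.
    solver_tol : float
        LP feasibility/optimality tolerance handed to the solver.
    """

    alpha: float = 1.0
    epsilon: float = 1e-6
    preset: str = FDH
    dtilde_convention: Convention = Convention.COLUMN_MAX
    tol_zero: float = 1e-7
    solver_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.preset not in (FDH, BCC, CCR):
            raise ValueError(f"unknown preset {self.preset!r}")
        object.__setattr__(self, "dtilde_convention", Convention(self.dtilde_convention))

    @property
    def ccr_active(self) -> bool:
        return self.preset == CCR

    @classmethod
    def fdh(cls, alpha: float = 1.0, **kw) -> "GDEAConfig":
        """Free-disposal-hull preset (α small-to-unit, T fixed at 0)."""
        return cls(alpha=alpha, preset=FDH, **kw)

    @classmethod
    def bcc(cls, alpha: float = LARGE_ALPHA, **kw) -> "GDEAConfig":
        """Variable-returns preset (large α, T fixed at 0)."""
        return cls(alpha=alpha, preset=BCC, **kw)

    @classmethod
    def ccr(cls, alpha: float = LARGE_ALPHA, **kw) -> "GDEAConfig":
        """Constant-returns preset (large α, free T / ratio constraint)."""
        return cls(alpha=alpha, preset=CCR, **kw)

    def with_(self, **kw) -> "GDEAConfig":
        return replace(self, **kw)

    def epsilon_bound(self, m: int, s: int) -> float:
        """Feasibility ceiling 1/(m+s) implied by the weight simplex."""
        return 1.0 / (m + s)
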