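"""Cutoff-dose logistic regression (CDLR) sigmoid: evaluation, inversion, slope.

The model expresses the normal tissue complication probability (NTCP) of an
organ at risk as a two-parameter logistic function of the absorbed dose ``D``
(in Gy)::

    NTCP(D) = 1 / (1 + exp(-D * beta + gamma))

``beta`` (1/Gy) controls the steepness of the dose-response curve and
``gamma`` (dimensionless) its offset; the curve crosses 50% at
``TD50 = gamma / beta``.  Dose constraints are read off the inverted curve:
``TDx`` is the dose at which the modelled complication probability equals
``x``.  The maximum slope ``m`` of the sigmoid occurs at TD50 and equals
``beta / 4`` analytically; following common practice in NTCP reporting it is
computed here by a numerical central difference at TD50.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "CDLRParams",
    "ConstraintReport",
    "ntcp",
    "tdx",
    "slope_at",
    "constraint_report",
]

#: Default step (Gy) of the central-difference slope estimate.  Small enough
#: to reproduce the analytic beta/4 at TD50 to better than 1e-6 for any
#: realistic beta, large enough to stay clear of floating-point cancellation.
DEFAULT_SLOPE_STEP = 0.01


@dataclass(frozen=True)
class CDLRParams:
    """The two parameters of the CDLR sigmoid.

    Parameters
    ----------
    beta : float
        Slope parameter, per Gy.  Positive for a biologically monotone
        increasing dose-response curve; evaluation does not require this,
        fitting enforces it.
    gamma : float
        Dimensionless offset; ``gamma / beta`` is the 50% dose (TD50).
    """

    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.beta) and math.isfinite(self.gamma)):
            raise ValueError(
                f"CDLR parameters must be finite, got beta={self.beta}, gamma={self.gamma}"
            )

    @property
    def td50(self) -> float:
        """Dose at 50% complication probability, ``gamma / beta`` (Gy)."""
        if self.beta == 0:
            raise ZeroDivisionError("TD50 is undefined for beta == 0")
        return self.gamma / self.beta

    def to_dict(self) -> dict:
        return {"beta": self.beta, "gamma": self.gamma}

    @classmethod
    def from_dict(cls, d: dict) -> "CDLRParams":
        return cls(beta=float(d["beta"]), gamma=float(d["gamma"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "CDLRParams":
        return cls.from_dict(json.loads(s))


def ntcp(dose, params: CDLRParams):
    """Evaluate the CDLR sigmoid at ``dose`` (Gy).

    Accepts a scalar or array dose and returns the complication probability
    ``1 / (1 + exp(-dose * beta + gamma))``.  Evaluation is numerically
    stable: very large exponents saturate towards 0 or 1 instead of
    overflowing.

    Raises
    ------
    ValueError
        If ``dose`` is non-finite or negative.
    """
    d = np.asarray(dose, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("dose must be finite")
    if np.any(d < 0):
        raise ValueError("dose must be >= 0 Gy")
    out = expit(d * params.beta - params.gamma)
    return float(out) if np.isscalar(dose) or out.ndim == 0 else out


def tdx(prob: float, params: CDLRParams) -> float:
    """Dose (Gy) at which the modelled complication probability equals ``prob``.

    Closed-form inversion of the sigmoid:
    ``dose = (gamma + logit(prob)) / beta``.

    Raises
    ------
    ValueError
        If ``prob`` is outside the open interval (0, 1), or ``beta == 0``
        (a flat curve has no inverse).
    """
    if not (0.0 < prob < 1.0):
        raise ValueError(f"target probability must lie in (0, 1), got {prob}")
    if params.beta == 0:
        raise ValueError("beta == 0: the flat curve cannot be inverted")
    return float((params.gamma + logit(prob)) / params.beta)


def slope_at(dose: float, params: CDLRParams, step: float = DEFAULT_SLOPE_STEP) -> float:
    """Numerical slope of the sigmoid at ``dose``, in probability per Gy.

    Central difference ``[NTCP(d + h) - NTCP(d - h)] / (2 h)``.  At TD50 this
    reproduces the analytic maximum slope ``beta / 4`` to well below 1e-6 for
    the default step of 0.01 Gy.
    """
    if not (step > 0):
        raise ValueError(f"step must be > 0, got {step}")
    lo = max(dose - step, 0.0)
    hi = dose + step
    return float((ntcp(hi, params) - ntcp(lo, params)) / (hi - lo))


@dataclass(frozen=True)
class ConstraintReport:
    """Derived dose-constraint quantities of a fitted CDLR curve.

    All values are stored at full double precision; the whole-Gy / 3-decimal
    rounding used in printed summaries is applied only at display time.
    """

    td25: float
    td50: float
    m: float
    ntcp_at: tuple = field(default_factory=tuple)  # ((dose Gy, probability), ...)

    def to_dict(self) -> dict:
        return {
            "td25": self.td25,
            "td50": self.td50,
            "m": self.m,
            "ntcp_at": [[d, p] for d, p in self.ntcp_at],
        }

    def summary(self) -> str:
        """Human-readable summary at the field's customary printed precision
        (whole Gy for doses, three decimals for the slope)."""
        lines = [
            f"TD25 = {self.td25:.0f} Gy",
            f"TD50 = {self.td50:.0f} Gy",
            f"m    = {self.m:.3f} per Gy",
        ]
        for d, p in self.ntcp_at:
            lines.append(f"NTCP({d:g} Gy) = {100 * p:.1f}%")
        return "\n".join(lines)


def constraint_report(params: CDLRParams, doses=()) -> ConstraintReport:
    """Derive TD25, TD50, the slope at TD50, and NTCP at requested doses.

    Raises
    ------
    ValueError
        If ``beta <= 0`` — the curve is not monotone increasing and dose
        constraints are meaningless.
    """
    if params.beta <= 0:
        raise ValueError(
            f"constraint derivation requires beta > 0 (monotone curve), got {params.beta}"
        )
    td50 = tdx(0.5, params)
    return ConstraintReport(
        td25=tdx(0.25, params),
        td50=td50,
        m=slope_at(td50, params),
        ntcp_at=tuple((float(d), ntcp(float(d), params)) for d in doses),
    )
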