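"""Count-weighted least-squares fitting of the CDLR sigmoid to binned data.

The fit minimises, over (beta, gamma),

    SSE(beta, gamma) = sum_i  n_i * (p_i - NTCP(d_i; beta, gamma))**2

where bin i contributes its observed incidence p_i at representative dose
d_i with weight n_i, the number of ears in the bin.  The incidences are used
directly as proportions (no logit transform), so bins at exactly 0 or 1 pose
no difficulty.

The optimiser is deterministic: a vectorised coarse grid over plausible
(beta, gamma) seeds a derivative-based local minimisation (L-BFGS-B with the
analytic gradient).  Two parameters against a handful of bins make the grid
cheap and the combination robust to the flat tails of the sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .binning import BinnedSeries
from .model import CDLRParams, ConstraintReport, constraint_report

__all__ = ["FitResult", "fit_cdlr", "weighted_sse", "InsufficientDataError"]

# Search box of the seeding grid; generous around clinically plausible
# dose-response steepness (beta up to 0.5/Gy) and offsets (TD50 up to tens
# of Gy).  The local refinement may leave the box.
GRID_BETA = (1e-3, 0.5)
GRID_GAMMA = (0.0, 20.0)
GRID_SIZE = 60

# beta is kept strictly positive during refinement: the dose-response curve
# of a toxicity is monotone increasing.
_BETA_FLOOR = 1e-9


class InsufficientDataError(ValueError):
    """Raised when a series has too few informative bins to fit."""


@dataclass(frozen=True)
class FitResult:
    """Fitted CDLR parameters plus goodness-of-fit and derived constraints."""

    params: CDLRParams
    weighted_sse: float
    n_bins: int
    bin_width: float
    metric: str
    converged: bool
    report: ConstraintReport

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "bin_width": self.bin_width,
            "beta": self.params.beta,
            "gamma": self.params.gamma,
            "m": self.report.m,
            "td25": self.report.td25,
            "td50": self.report.td50,
            "weighted_sse": self.weighted_sse,
            "n_bins": self.n_bins,
            "converged": self.converged,
        }


def _arrays(series: BinnedSeries):
    d = np.array([b.dose_rep for b in series.bins], dtype=float)
    p = np.array([b.incidence for b in series.bins], dtype=float)
    w = np.array([b.n_total for b in series.bins], dtype=float)
    return d, p, w


def weighted_sse(series: BinnedSeries, params: CDLRParams) -> float:
    """Sum over bins of ``n_total * (incidence - NTCP(dose_rep))**2``.

    Zero exactly when the curve interpolates every bin incidence.
    """
    d, p, w = _arrays(series)
    r = p - expit(d * params.beta - params.gamma)
    return float(np.sum(w * r * r))


def _objective_and_grad(theta, d, p, w):
    beta, gamma = theta
    mu = expit(d * beta - gamma)
    r = p - mu
    dmu = mu * (1.0 - mu)  # derivative of expit wrt its argument
    common = -2.0 * w * r * dmu
    return float(np.sum(w * r * r)), np.array(
        [np.sum(common * d), np.sum(-common)]
    )


def _grid_seed(d, p, w):
    betas = np.linspace(*GRID_BETA, GRID_SIZE)
    gammas = np.linspace(*GRID_GAMMA, GRID_SIZE)
    # residual cube: (beta, gamma, bin)
    mu = expit(d[None, None, :] * betas[:, None, None] - gammas[None, :, None])
    sse = np.einsum("k,ijk->ij", w, (p[None, None, :] - mu) ** 2)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return np.array([betas[i], gammas[j]])


def _moment_seed(d, p, w):
    span = d.max() - d.min()
    beta0 = max(4.0 * (p.max() - p.min()) / span, _BETA_FLOOR) if span > 0 else 0.05
    gamma0 = beta0 * float(np.median(d))
    return np.array([beta0, gamma0])


def fit_cdlr(series: BinnedSeries, init: Optional[CDLRParams] = None) -> FitResult:
    """Fit the CDLR sigmoid to a binned incidence series by weighted LS.

    Parameters
    ----------
    series : BinnedSeries
        Must contain at least two bins with distinct representative doses.
    init : CDLRParams, optional
        Starting point for the local minimisation.  When omitted the start
        is chosen by a coarse grid search; the fit is deterministic either
        way.

    Returns
    -------
    FitResult
        Fitted parameters, the achieved weighted SSE, and the derived
        constraint report (TD25, TD50, slope m).  Failure of the local
        optimiser to report convergence is flagged, never silent.

    Raises
    ------
    InsufficientDataError
        Fewer than two bins, or all representative doses identical.
    """
    d, p, w = _arrays(series)
    if len(d) < 2 or np.unique(d).size < 2:
        raise InsufficientDataError(
            f"need >= 2 bins with distinct doses to fit, got {len(d)}"
        )

    x0 = np.array([init.beta, init.gamma]) if init is not None else _grid_seed(d, p, w)
    x0[0] = max(x0[0], _BETA_FLOOR)

    res = minimize(
        _objective_and_grad,
        x0,
        args=(d, p, w),
        jac=True,
        method="L-BFGS-B",
        bounds=[(_BETA_FLOOR, None), (None, None)],
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
    )
    # polish from the moment start as well and keep the better optimum; both
    # starts are deterministic, so the fit is too
    if init is None:
        res2 = minimize(
            _objective_and_grad,
            _moment_seed(d, p, w),
            args=(d, p, w),
            jac=True,
            method="L-BFGS-B",
            bounds=[(_BETA_FLOOR, None), (None, None)],
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
        )
        if res2.fun < res.fun:
            res = res2

    params = CDLRParams(beta=float(res.x[0]), gamma=float(res.x[1]))
    return FitResult(
        params=params,
        weighted_sse=float(res.fun),
        n_bins=len(d),
        bin_width=series.bin_width,
        metric=series.metric,
        converged=bool(res.success),
        report=constraint_report(params),
    )
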