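"""Fitting the three log-log incidence models and selecting among them.

The linear model is ordinary least squares of ln I on ln t.  The curved
models use a hybrid scheme: an anchor OLS on the distinctly linear early
age classes fixes (a0, a1), and the curvature coefficients (a2, a3) then
come from a second linear regression on algebraically transformed
residuals — for the concave model ln(e^d - 1) = ln a2 + a3 ln t where d
is the residual from the linear part, and ln(1 - e^d) for the convex
model.  Because early classes are never entirely curvature-free, the
staged estimate is then refined over all points (see the implementation
note below), which recovers exact coefficients on noise-free data.

Model choice follows the coefficient of determination on the ln scale,
with a parsimony tie-break: the two-parameter linear model wins unless a
four-parameter curved fit beats it by more than ``tie_tolerance``.
"""

# Implementation note on the curved fit: the two hybrid stages alone do not
# return exact coefficients even on noise-free data, because no prefix of
# age classes is entirely curvature-free (the anchor OLS absorbs part of
# the curvature term into a0, a1), and simply alternating the two linear
# stages oscillates.  Each anchor size therefore seeds a Levenberg-
# Marquardt refinement of all four coefficients on the ln-scale
# residuals; the hybrid supplies the starting values and the anchor scan
# supplies multi-start robustness.

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy import stats

from .models import CurvedParams, Curvature, LinearParams
from .series import IncidenceSeries

logger = logging.getLogger(__name__)

ModelKind = str  # "linear", "convex", "concave"


class FitError(RuntimeError):
    """A model could not be fitted to the series."""


class CurvatureMismatchError(FitError):
    """Residual signs are incompatible with the requested curvature."""


@dataclass(frozen=True)
class FitResult:
    """One fitted model: kind, coefficients, fit quality, residuals.

    ``residuals`` are observed minus predicted ln-incidence at the usable
    (positive-incidence) age classes.  ``anchor_size`` is the number of
    early points used by the linear stage of a curved fit (None for
    linear fits).
    """

    model_kind: ModelKind
    params: Union[LinearParams, CurvedParams]
    r_squared: float
    residuals: np.ndarray
    t_used: np.ndarray
    anchor_size: Optional[int] = None

    @property
    def n_points(self) -> int:
        return len(self.t_used)


@dataclass(frozen=True)
class SelectionResult:
    """All attempted fits plus the chosen model kind."""

    fits: Dict[ModelKind, FitResult]
    failures: Dict[ModelKind, str]
    chosen: ModelKind
    tie_tolerance: float

    @property
    def best(self) -> FitResult:
        return self.fits[self.chosen]


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on the ln scale."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("need equal-length inputs with >= 2 points")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero variance in observed values: R^2 undefined")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def _usable_log_data(series: IncidenceSeries) -> Tuple[np.ndarray, np.ndarray]:
    """Return (ln t, ln I) at positive-incidence classes, warning on drops."""
    mask = series.positive_mask()
    if not mask.all():
        dropped = series.t[~mask].astype(int).tolist()
        logger.warning(
            "series %s: excluding zero-incidence age classes %s from fit",
            series.key, dropped,
        )
    return np.log(series.t[mask]), np.log(series.rate[mask])


def fit_linear(series: IncidenceSeries) -> FitResult:
    """OLS of ln I on ln t; slope + 1 = r, exp(intercept) = k."""
    x, y = _usable_log_data(series)
    if len(x) < 3:
        raise FitError(
            f"series {series.key}: need >= 3 positive-incidence classes, have {len(x)}"
        )
    ls = stats.linregress(x, y)
    pred = ls.intercept + ls.slope * x
    return FitResult(
        model_kind="linear",
        params=LinearParams.from_slope_intercept(ls.slope, ls.intercept),
        r_squared=r_squared(y, pred) if np.ptp(y) > 0 else 1.0,
        residuals=y - pred,
        t_used=np.exp(x),
    )


def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """(intercept, slope) by least squares; exact solution for 2 points."""
    if len(x) == 2:  # algebraic two-point solution
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return y[0] - slope * x[0], slope
    ls = stats.linregress(x, y)
    return ls.intercept, ls.slope


def _curvature_stage(
    x: np.ndarray, d: np.ndarray, curvature: Curvature
) -> Tuple[float, float]:
    """Solve (a2, a3) from residuals d = ln I - (a0 + a1 ln t).

    Concave: d = ln(1 + a2 t^a3) > 0, so ln(e^d - 1) = ln a2 + a3 ln t.
    Convex:  d = ln(1 - a2 t^a3) < 0, so ln(1 - e^d) = ln a2 + a3 ln t.
    Points whose residual sign is incompatible with the curvature carry
    no usable information and are dropped; fewer than 2 compatible
    points is a curvature mismatch.
    """
    if curvature == "concave":
        valid = d > 0
        z = np.expm1(d[valid])
    else:
        valid = d < 0
        z = -np.expm1(d[valid])
    if valid.sum() < 2:
        raise CurvatureMismatchError(
            f"only {int(valid.sum())} residuals have the sign required by a "
            f"{curvature} curvature term; the series shows no such curvature"
        )
    b0, b1 = _ols(x[valid], np.log(z))
    return math.exp(b0), b1


def _clip_convex(a2: float, a3: float, t: np.ndarray, curvature: Curvature) -> float:
    """Keep the convex log argument positive for a starting estimate."""
    if curvature == "convex":
        limit = 0.999999 / np.max(t ** a3)
        return min(a2, limit)
    return a2


def _polish(
    x: np.ndarray,
    y: np.ndarray,
    t: np.ndarray,
    curvature: Curvature,
    start: Tuple[float, float, float, float],
) -> Tuple[float, float, float, float, float]:
    """Levenberg-Marquardt refinement of (a0, a1, a2, a3) on ln residuals.

    a2 is optimised on the log scale to stay positive; a non-positive
    convex log argument is penalised so the search cannot leave the
    model's domain.  Returns the coefficients and the residual SSR.
    """
    from scipy.optimize import least_squares

    sign = -1.0 if curvature == "convex" else 1.0
    a0, a1, a2, a3 = start

    def resid(theta: np.ndarray) -> np.ndarray:
        b0, b1, log_b2, b3 = theta
        with np.errstate(over="ignore", invalid="ignore"):
            arg = 1.0 + sign * np.exp(log_b2) * t ** b3
            out = np.where(
                arg > 1e-12,
                b0 + b1 * x + np.log(np.maximum(arg, 1e-12)) - y,
                1e6,
            )
        return np.nan_to_num(out, nan=1e6, posinf=1e6, neginf=-1e6)

    sol = least_squares(
        resid,
        np.array([a0, a1, math.log(max(a2, 1e-12)), a3]),
        method="lm",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=20000,  # small-a3 valleys are ill-conditioned and need room
    )
    b0, b1, log_b2, b3 = sol.x
    return b0, b1, math.exp(log_b2), b3, float(np.sum(sol.fun ** 2))


def fit_curved(
    series: IncidenceSeries,
    curvature: Curvature,
    *,
    anchor_min: int = 3,
) -> FitResult:
    """Hybrid linear-plus-algebraic fit of a curved log-log model.

    For every anchor prefix of the earliest m points (m = anchor_min ..
    n-2) — early because the curvature term grows with age class in both
    curved families — an anchor OLS gives (a0, a1), the algebraic
    transform of the later residuals gives (a2, a3) by a second linear
    regression, and a Levenberg-Marquardt pass over all points refines
    the four coefficients.  The anchor whose refined fit has the lowest
    ln-scale SSR wins; global R^2 is scored over all usable points.

    Raises
    ------
    CurvatureMismatchError
        If no anchor leaves >= 2 later residuals with the sign the
        requested curvature demands (the series shows no such curvature).
    """
    x, y = _usable_log_data(series)
    n = len(x)
    if n < 5:
        raise FitError(
            f"series {series.key}: curved fit needs >= 5 usable classes "
            f"(>= 3 anchor + >= 2 curvature), have {n}"
        )
    t = np.exp(x)

    best = None
    mismatch: Optional[CurvatureMismatchError] = None
    for m in range(anchor_min, n - 1):
        a0, a1 = _ols(x[:m], y[:m])
        d_tail = y[m:] - (a0 + a1 * x[m:])
        try:
            a2, a3 = _curvature_stage(x[m:], d_tail, curvature)
        except CurvatureMismatchError as exc:
            mismatch = exc
            continue
        a2 = _clip_convex(a2, a3, t, curvature)
        b0, b1, b2, b3, ssr = _polish(x, y, t, curvature, (a0, a1, a2, a3))
        if best is None or ssr < best[0]:
            best = (ssr, m, b0, b1, b2, b3)
    if best is None:
        assert mismatch is not None
        raise mismatch
    _, m, a0, a1, a2, a3 = best

    params = CurvedParams(a0=a0, a1=a1, a2=a2, a3=a3, curvature=curvature)
    with np.errstate(invalid="ignore"):
        pred = a0 + a1 * x + np.log1p(params.sign * a2 * t ** a3)
    return FitResult(
        model_kind=curvature,
        params=params,
        r_squared=r_squared(y, pred),
        residuals=y - pred,
        t_used=t,
        anchor_size=m,
    )


def select_model(
    series: IncidenceSeries, tie_tolerance: float = 0.005
) -> SelectionResult:
    """Fit all three models and choose by R^2 with a parsimony tie-break.

    Curved fits are allowed to fail (recorded, not fatal).  The linear
    model is preferred whenever the best curved R^2 exceeds it by no more
    than ``tie_tolerance``.
    """
    fits: Dict[ModelKind, FitResult] = {}
    failures: Dict[ModelKind, str] = {}
    try:
        fits["linear"] = fit_linear(series)
    except (FitError, ValueError) as exc:
        failures["linear"] = str(exc)
    for curvature in ("convex", "concave"):
        try:
            fits[curvature] = fit_curved(series, curvature)
        except (FitError, ValueError) as exc:
            failures[curvature] = str(exc)
    if not fits:
        raise FitError(f"series {series.key}: all model fits failed: {failures}")
    best_kind = max(fits, key=lambda kind: fits[kind].r_squared)
    if (
        "linear" in fits
        and best_kind != "linear"
        and fits[best_kind].r_squared - fits["linear"].r_squared <= tie_tolerance
    ):
        best_kind = "linear"
    return SelectionResult(
        fits=fits, failures=failures, chosen=best_kind, tie_tolerance=tie_tolerance
    )
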