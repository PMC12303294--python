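"""Core equations of the multistage (Armitage-Doll-type) incidence framework.

The age-specific incidence rate I(t) of a disease that requires ``r``
sequential, irreversible, rate-limiting events follows a power law in age,
which is linear on the log-log scale:

    ln I(t) = (r - 1) ln t + ln k

where ``k`` aggregates the per-event rates.  Two four-parameter
generalisations bend this line at older ages: a convex-upwards form
``ln I = a0 + a1 ln t + ln(1 - a2 t^a3)`` and a concave-upwards form
``ln I = a0 + a1 ln t + ln(1 + a2 t^a3)``.  Either curvature admits two
mechanistic readings: population heterogeneity (two subgroups with rates
k_p, k_q scaling as t^p, t^q) or an age-related effect (a single pathway
modified by a decelerating or accelerating factor).

This module is a pure computational layer: parameter containers, forward
model evaluation, the ordered-event probability calculus, the maps between
fitted coefficients and mechanistic quantities, and time-rescaling algebra.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

Curvature = Literal["convex", "concave"]
InterpretationMode = Literal["heterogeneity", "age_effect"]

#: k_i * t_max at or above this triggers a rare-event warning: the power-law
#: approximation assumes each event is individually unlikely over a lifetime.
RARE_EVENT_THRESHOLD = 1.0


class DomainError(ValueError):
    """Model evaluated outside its mathematical domain."""


@dataclass(frozen=True)
class LinearParams:
    """Parameters of the linear log-log model ln I(t) = (r-1) ln t + ln k.

    Attributes
    ----------
    r : float
        Number of rate-limiting events.  Fitted values are real-valued;
        non-integer values are meaningful ("3 to 4 steps").
    k : float
        Aggregated probability per unit time of the full ordered event
        sequence; the model intercept is ln k.
    """

    r: float
    k: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")

    @property
    def slope(self) -> float:
        return self.r - 1.0

    @property
    def intercept(self) -> float:
        return math.log(self.k)

    @classmethod
    def from_slope_intercept(cls, slope: float, intercept: float) -> "LinearParams":
        return cls(r=slope + 1.0, k=math.exp(intercept))


@dataclass(frozen=True)
class CurvedParams:
    """Coefficients of a curved log-log model.

    ``ln I(t) = a0 + a1 ln t + ln(1 -+ a2 t^a3)`` with ``-`` for convex
    and ``+`` for concave curvature.  The convex form is only defined
    while ``a2 * t**a3 < 1``; that is checked at evaluation time because
    validity depends on the age range, not the coefficients alone.
    """

    a0: float
    a1: float
    a2: float
    a3: float
    curvature: Curvature

    def __post_init__(self) -> None:
        if self.a2 < 0:
            raise ValueError(f"a2 must be >= 0, got {self.a2}")
        if self.curvature not in ("convex", "concave"):
            raise ValueError(f"unknown curvature {self.curvature!r}")

    @property
    def sign(self) -> float:
        """Sign of the curvature term inside the logarithm."""
        return -1.0 if self.curvature == "convex" else 1.0


@dataclass(frozen=True)
class MultistageRates:
    """Per-event occurrence rates k_1..k_r of an ordered event sequence.

    Each rate is a probability per unit time; ``r = len(rates)`` is the
    number of required events.  The power-law incidence approximation
    assumes every event is rare over the observation window; use
    :meth:`check_rare` to flag violations.
    """

    rates: tuple

    def __init__(self, rates: Sequence[float]) -> None:
        rates = tuple(float(x) for x in rates)
        if len(rates) == 0:
            raise ValueError("at least one rate is required")
        if any(x <= 0 for x in rates):
            raise ValueError(f"all rates must be > 0, got {rates}")
        object.__setattr__(self, "rates", rates)

    @property
    def r(self) -> int:
        return len(self.rates)

    def check_rare(self, t_max: float) -> bool:
        """Warn (and return False) if any k_i * t_max >= 1.

        Beyond that point the linearised per-event probability k_i * t is
        no longer a probability and the t^(r-1) hazard approximation
        degrades.
        """
        worst = max(self.rates) * t_max
        if worst >= RARE_EVENT_THRESHOLD:
            warnings.warn(
                f"max(k_i) * t_max = {worst:.3g} >= {RARE_EVENT_THRESHOLD}; "
                "the rare-event power-law approximation is unreliable",
                stacklevel=2,
            )
            return False
        return True


@dataclass(frozen=True)
class ScaleTransform:
    """Multiplicative rescaling of the age axis, t -> w * t."""

    w: float

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise DomainError(f"scale factor w must be > 0, got {self.w}")


@dataclass(frozen=True)
class MechanisticParams:
    """Biological quantities behind a fitted curved model.

    Under the heterogeneity reading the population has two subgroups (or
    pathways) with sequence probabilities k_p, k_q whose risks scale as
    t^p and t^q; the shared step count is r.  Under the age-effect reading
    a single pathway with aggregated probability k_p (= k of the linear
    model) is modified by a decelerating factor (convex: rate k_d,
    exponent d) or an accelerating factor (concave: rate k_a, exponent a).
    """

    mode: InterpretationMode
    curvature: Curvature
    k_p: float
    r: float
    # heterogeneity reading
    k_q: Optional[float] = None
    p: Optional[float] = None
    q: Optional[float] = None
    # age-effect reading: modifier rate and exponent (k_d/d for convex
    # deceleration, k_a/a for concave acceleration)
    k_mod: Optional[float] = None
    exp_mod: Optional[float] = None

    def to_curved(self) -> CurvedParams:
        """Re-assemble the fitted coefficients (inverse of the mapping)."""
        if self.mode == "heterogeneity":
            assert self.k_q is not None and self.p is not None and self.q is not None
            return CurvedParams(
                a0=math.log(self.k_p),
                a1=self.r + self.p - 1.0,
                a2=self.k_q / self.k_p,
                a3=self.q - self.p,
                curvature=self.curvature,
            )
        assert self.k_mod is not None and self.exp_mod is not None
        return CurvedParams(
            a0=math.log(self.k_p),
            a1=self.r - 1.0,
            a2=self.k_mod / self.k_p,
            a3=self.exp_mod - self.r + 1.0,
            curvature=self.curvature,
        )


def _check_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise DomainError(f"age class t must be > 0, got {t[t <= 0]}")
    return t


def linear_log_incidence(t, params: LinearParams):
    """ln I(t) = (r - 1) ln t + ln k.  Accepts scalar or array t > 0."""
    t = _check_t(t)
    out = params.slope * np.log(t) + params.intercept
    return out.item() if out.ndim == 0 else out


def curved_log_incidence(t, params: CurvedParams):
    """ln I(t) = a0 + a1 ln t + ln(1 -+ a2 t^a3).

    Raises
    ------
    DomainError
        For convex curvature at any t with a2 * t**a3 >= 1 (the log
        argument would be non-positive).
    """
    t = _check_t(t)
    term = params.a2 * t ** params.a3
    if params.curvature == "convex" and np.any(term >= 1.0):
        bad = np.atleast_1d(t)[np.atleast_1d(term) >= 1.0]
        raise DomainError(
            f"convex model undefined at t={bad.tolist()}: a2*t^a3 >= 1"
        )
    out = params.a0 + params.a1 * np.log(t) + np.log1p(params.sign * term)
    return out.item() if out.ndim == 0 else out


def unordered_event_probability(rates: MultistageRates, t: float) -> float:
    """Probability that the first r-1 events all occur (any order) by time t.

    Each event contributes its linearised probability k_i * t, so the
    product is (k_1 ... k_{r-1}) t^(r-1).  For r = 1 the product is empty
    and the value is 1.
    """
    if t < 0:
        raise DomainError(f"duration t must be >= 0, got {t}")
    return float(np.prod([k * t for k in rates.rates[:-1]]))


def ordered_event_probability(rates: MultistageRates, t: float) -> float:
    """As :func:`unordered_event_probability` but requiring one specific
    order out of the (r-1)! permutations."""
    return unordered_event_probability(rates, t) / math.factorial(rates.r - 1)


def aggregate_k(rates: MultistageRates) -> float:
    """Aggregated probability k multiplying t^(r-1) in the hazard.

    The first r-1 events must have occurred in order by age t
    (probability k_1...k_{r-1} t^(r-1) / (r-1)!) and the r-th event then
    strikes at rate k_r, so I(t) = k t^(r-1) with
    k = k_1...k_{r-1} k_r / (r-1)!.
    """
    return float(np.prod(rates.rates)) / math.factorial(rates.r - 1)


def rescale_time(params: LinearParams, xform: ScaleTransform) -> LinearParams:
    """Express the linear model on a rescaled age axis t' = w * t.

    Adjacent age classes come to differ by w units instead of one, which
    divides k by w^(r-1): the intercept shifts to ln k - (r-1) ln w while
    the slope r - 1 is untouched.  Consequently registry age *classes*
    (unit-spaced relabellings of unequal-width age groups) leave the
    estimated step count r unaffected.
    """
    new_intercept = params.intercept - params.slope * math.log(xform.w)
    return LinearParams.from_slope_intercept(params.slope, new_intercept)


def map_curved_to_mechanistic(
    params: CurvedParams,
    mode: InterpretationMode,
    *,
    p: Optional[float] = None,
    r: Optional[float] = None,
) -> MechanisticParams:
    """Translate fitted curved coefficients into mechanistic quantities.

    Heterogeneity mode solves  a0 = ln k_p, a1 = r + p - 1, a2 = k_q/k_p,
    a3 = q - p.  Since a1 pins down only the sum r + p, the caller must
    fix exactly one of ``p`` (subgroup age-scaling exponent) or ``r``
    (step count); the other is solved from a1.

    Age-effect mode reads  a1 = r - 1  directly (so neither ``p`` nor
    ``r`` may be supplied) and interprets the curvature term as a
    modifying factor: a2 = k_d/k with a3 = d - r + 1 for convex
    deceleration, or a2 = k_a/k with a3 = a - r + 1 for concave
    acceleration.
    """
    k_p = math.exp(params.a0)
    if mode == "heterogeneity":
        if (p is None) == (r is None):
            raise ValueError(
                "heterogeneity mode needs exactly one of p or r; "
                "(r, p) are not jointly identifiable from a1 = r + p - 1"
            )
        if p is None:
            p = params.a1 - r + 1.0
        else:
            r = params.a1 - p + 1.0
        return MechanisticParams(
            mode="heterogeneity",
            curvature=params.curvature,
            k_p=k_p,
            r=r,
            k_q=params.a2 * k_p,
            p=p,
            q=params.a3 + p,
        )
    if mode == "age_effect":
        if p is not None or r is not None:
            raise ValueError(
                "age_effect mode determines r = a1 + 1 from the fit; "
                "do not supply p or r"
            )
        r_eff = params.a1 + 1.0
        return MechanisticParams(
            mode="age_effect",
            curvature=params.curvature,
            k_p=k_p,
            r=r_eff,
            k_mod=params.a2 * k_p,
            exp_mod=params.a3 + r_eff - 1.0,
        )
    raise ValueError(f"unknown interpretation mode {mode!r}")
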