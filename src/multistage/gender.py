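"""Combined-gender incidence algebra and slope intermediacy.

The both-genders incidence at each age class is the arithmetic mean of
the female and male rates, I_fm = (I_f + I_m) / 2.  Between any two age
classes the combined log-log slope can be written two equivalent ways as
a gender slope plus a correction involving only the male/female
incidence ratios:

    S_fm = S_f + ln[(1 + I_m2/I_f2) / (1 + I_m1/I_f1)] / dln t
    S_fm = S_m + ln[(1 + I_f2/I_m2) / (1 + I_f1/I_m1)] / dln t

Whichever gender has the steeper line has the faster-growing ratio, so
one correction is positive and the other negative: the combined slope is
strictly between the gender slopes whenever they differ, and equal to
both when they coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np

from .series import IncidenceSeries


@dataclass(frozen=True)
class SlopeTriple:
    """Log-log slopes between two age classes for female, male, combined.

    ``s_fm`` is computed directly from the combined series; the dual
    routes via the female and male corrections are checked against it at
    construction time.  ``intermediate`` records whether s_fm lies
    strictly between s_f and s_m (it always does when s_f != s_m).
    """

    s_f: float
    s_m: float
    s_fm: float
    t_pair: Tuple[float, float]
    intermediate: bool


def combine_genders(
    female: IncidenceSeries, male: IncidenceSeries
) -> IncidenceSeries:
    """Both-genders series: per-class arithmetic mean of the two rates."""
    if female.age_class != male.age_class:
        raise ValueError(
            f"age classes differ: female {female.age_class} vs male {male.age_class}"
        )
    combined = 0.5 * (female.rate + male.rate)
    return replace(
        female, gender="both", incidence=tuple(combined),
        cancer=female.cancer or male.cancer,
    )


def pairwise_slope(series: IncidenceSeries, t1: int, t2: int) -> float:
    """Two-point log-log slope (ln I(t2) - ln I(t1)) / (ln t2 - ln t1)."""
    if t1 == t2:
        raise ValueError("t1 and t2 must differ")
    if t2 < t1:
        t1, t2 = t2, t1
    try:
        i1 = series.incidence[series.age_class.index(t1)]
        i2 = series.incidence[series.age_class.index(t2)]
    except ValueError as exc:
        raise ValueError(f"age class missing from series {series.key}") from exc
    if i1 <= 0 or i2 <= 0:
        raise ValueError(
            f"zero incidence at t={t1 if i1 <= 0 else t2}: log slope undefined"
        )
    return (math.log(i2) - math.log(i1)) / (math.log(t2) - math.log(t1))


def slope_triple(
    female: IncidenceSeries,
    male: IncidenceSeries,
    t1: int,
    t2: int,
    rtol: float = 1e-9,
) -> SlopeTriple:
    """Female, male and combined slopes between two age classes.

    The combined slope is computed from the mean series and re-derived
    through both correction-term routes; a discrepancy beyond ``rtol``
    (which would indicate an implementation fault, not a data property)
    raises.
    """
    combined = combine_genders(female, male)
    s_f = pairwise_slope(female, t1, t2)
    s_m = pairwise_slope(male, t1, t2)
    s_fm = pairwise_slope(combined, t1, t2)

    dlnt = math.log(max(t1, t2)) - math.log(min(t1, t2))
    lo, hi = min(t1, t2), max(t1, t2)
    if1 = female.incidence[female.age_class.index(lo)]
    if2 = female.incidence[female.age_class.index(hi)]
    im1 = male.incidence[male.age_class.index(lo)]
    im2 = male.incidence[male.age_class.index(hi)]
    via_f = s_f + math.log((1 + im2 / if2) / (1 + im1 / if1)) / dlnt
    via_m = s_m + math.log((1 + if2 / im2) / (1 + if1 / im1)) / dlnt
    scale = max(1.0, abs(s_fm))
    if abs(via_f - s_fm) > rtol * scale or abs(via_m - s_fm) > rtol * scale:
        raise RuntimeError(
            f"combined-slope identity violated: direct {s_fm}, "
            f"via female {via_f}, via male {via_m}"
        )
    intermediate = min(s_f, s_m) < s_fm < max(s_f, s_m)
    return SlopeTriple(
        s_f=s_f, s_m=s_m, s_fm=s_fm, t_pair=(lo, hi), intermediate=intermediate
    )


def slope_triples(
    female: IncidenceSeries, male: IncidenceSeries
) -> List[SlopeTriple]:
    """Slope triples for every consecutive pair of age classes."""
    return [
        slope_triple(female, male, t1, t2)
        for t1, t2 in zip(female.age_class, female.age_class[1:])
    ]
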