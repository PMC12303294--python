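"""Synthetic incidence series and multistage cohort simulation.

Two generators stand in for registry data:

* :func:`generate_series` evaluates one of the three log-log models on a
  grid of age classes and adds Gaussian noise on the ln-incidence scale
  (multiplicative lognormal noise on the natural scale, conjugate to
  fitting on the log scale).

* :func:`simulate_cohort` draws individual disease-onset ages as sums of
  ordered exponential waiting times, one per rate-limiting event; each
  event's clock starts when the previous event completes, which realises
  the required event order directly.  :func:`estimate_hazard` then
  recovers the age-specific incidence rate (a hazard) from the simulated
  onsets by binned occurrence/exposure estimation, closing the loop back
  to the power law I(t) ~ k t^(r-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .models import CurvedParams, LinearParams, MultistageRates, DomainError, \
    aggregate_k, curved_log_incidence, linear_log_incidence
from .series import IncidenceSeries

ModelParams = Union[LinearParams, CurvedParams]

DEFAULT_AGE_CLASSES: Tuple[int, ...] = tuple(range(1, 9))


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for one synthetic incidence series.

    ``age_classes`` defaults to 1..8, mirroring the eight registry age
    groups (0-14, 15-39, then five-year bands up to 65-69) after unit
    relabelling.  ``noise_sd`` is the standard deviation of additive
    Gaussian noise on ln I.
    """

    params: ModelParams
    age_classes: Tuple[int, ...] = DEFAULT_AGE_CLASSES
    noise_sd: float = 0.0
    seed: int = 0
    cancer: str = "synthetic"
    gender: str = "both"

    def __post_init__(self) -> None:
        ages = tuple(int(a) for a in self.age_classes)
        if len(ages) == 0 or ages[0] < 1:
            raise ValueError("age_classes must be non-empty and start >= 1")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("age_classes must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "age_classes", ages)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a simulated cohort of individuals at risk.

    Follow-up is censored at ``max_age``; ``n_bins`` equal-width bins
    partition (0, max_age] for hazard estimation.
    """

    rates: MultistageRates
    n_individuals: int
    max_age: float
    n_bins: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not self.max_age > 0:
            raise ValueError("max_age must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True)
class CohortResult:
    """Onset ages from a cohort simulation.

    ``onset_age`` holds the latent age at which the final rate-limiting
    event completed; ``censored`` marks individuals whose onset fell
    beyond the follow-up window.  ``observed_age`` is onset truncated at
    max_age (the exposure time actually contributed).
    """

    onset_age: np.ndarray
    censored: np.ndarray
    max_age: float

    @property
    def observed_age(self) -> np.ndarray:
        return np.minimum(self.onset_age, self.max_age)

    @property
    def n_events(self) -> int:
        return int((~self.censored).sum())


@dataclass(frozen=True)
class HazardEstimate:
    """Binned occurrence/exposure hazard estimates.

    ``hazard`` is events / person-time per bin; bins with zero
    person-time are undefined (NaN) and flagged in ``undefined`` rather
    than dropped.  ``se`` is the Poisson standard error
    sqrt(events)/person-time.
    """

    bin_edges: np.ndarray
    events: np.ndarray
    person_time: np.ndarray
    hazard: np.ndarray
    se: np.ndarray
    undefined: np.ndarray

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def model_log_incidence(t, params: ModelParams):
    """Evaluate whichever model ``params`` describes at age classes t."""
    if isinstance(params, LinearParams):
        return linear_log_incidence(t, params)
    return curved_log_incidence(t, params)


def generate_series(spec: SeriesSpec) -> IncidenceSeries:
    """Draw one incidence series from the model in ``spec``.

    ln I at each age class is the exact model prediction plus an
    independent N(0, noise_sd^2) deviate; the returned series carries the
    natural-scale incidence exp(ln I).  Deterministic given ``spec.seed``.

    Raises
    ------
    DomainError
        If convex parameters violate a2 * t^a3 < 1 at any requested age
        class (the error names the offending classes).
    """
    t = np.asarray(spec.age_classes, dtype=float)
    log_i = np.asarray(model_log_incidence(t, spec.params), dtype=float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        log_i = log_i + rng.normal(0.0, spec.noise_sd, size=log_i.shape)
    return IncidenceSeries(
        cancer=spec.cancer,
        gender=spec.gender,
        age_class=spec.age_classes,
        incidence=tuple(np.exp(log_i)),
    )


def generate_gender_pair(
    female: SeriesSpec, male: SeriesSpec
) -> Tuple[IncidenceSeries, IncidenceSeries, IncidenceSeries]:
    """Generate a female and a male series plus their combined series.

    The combined ("both genders") incidence at each age class is the
    arithmetic mean (I_f + I_m) / 2, the convention under which the
    combined log-log slope is intermediate between the gender slopes.
    """
    if female.age_classes != male.age_classes:
        raise ValueError(
            "female and male specs must share age classes, got "
            f"{female.age_classes} vs {male.age_classes}"
        )
    f = generate_series(female)
    m = generate_series(male)
    # local import: gender module depends on series only, no cycle in practice
    from .gender import combine_genders

    return f, m, combine_genders(f, m)


def simulate_cohort(spec: CohortSpec) -> CohortResult:
    """Simulate disease onset ages for a cohort of individuals.

    Each individual accrues the r rate-limiting events strictly in
    order: waiting time i is exponential with rate k_i and starts when
    event i-1 completes, so the onset age is the sum of r independent
    exponential variables.  Onsets beyond max_age are censored.
    Deterministic given ``spec.seed``: all waiting times come from one
    seeded generator in a fixed (n_individuals, r) layout.
    """
    spec.rates.check_rare(spec.max_age)
    rng = np.random.default_rng(spec.seed)
    scales = 1.0 / np.asarray(spec.rates.rates)
    waits = rng.exponential(scales, size=(spec.n_individuals, spec.rates.r))
    onset = waits.sum(axis=1)
    return CohortResult(
        onset_age=onset, censored=onset > spec.max_age, max_age=spec.max_age
    )


def estimate_hazard(result: CohortResult, spec: CohortSpec) -> HazardEstimate:
    """Occurrence/exposure hazard on ``spec.n_bins`` bins over (0, max_age].

    Every individual contributes person-time to each bin up to their exit
    (onset or censoring); censored individuals contribute exposure but no
    event.  Bins with zero person-time yield NaN hazard and are flagged.

    Raises
    ------
    ValueError
        If no uncensored onset exists (nothing to estimate).
    """
    if result.n_events == 0:
        raise ValueError("no uncensored onsets; hazard is inestimable")
    edges = np.linspace(0.0, spec.max_age, spec.n_bins + 1)
    exit_age = result.observed_age
    event_age = result.onset_age[~result.censored]
    events, _ = np.histogram(event_age, bins=edges)
    # person-time in bin b: sum over individuals of overlap of (0, exit] with bin
    lo = edges[:-1][None, :]
    hi = edges[1:][None, :]
    overlap = np.clip(exit_age[:, None], lo, hi) - lo
    person_time = overlap.sum(axis=0)
    undefined = person_time <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        hazard = np.where(undefined, np.nan, events / person_time)
        se = np.where(undefined, np.nan, np.sqrt(events) / person_time)
    return HazardEstimate(
        bin_edges=edges,
        events=events,
        person_time=person_time,
        hazard=hazard,
        se=se,
        undefined=undefined,
    )


def hazard_loglog_slope(
    est: HazardEstimate, min_events: int = 1
) -> Tuple[float, float]:
    """Weighted log-log regression of binned hazard on bin midpoints.

    Returns (slope, intercept) of ln hazard on ln t over bins with at
    least ``min_events`` events, weighting each bin by its event count
    (the inverse variance of ln hazard under Poisson counts).  For a
    multistage process in the rare-event regime the slope estimates
    r - 1 and the intercept estimates ln(aggregate_k).
    """
    use = (est.events >= max(min_events, 1)) & ~est.undefined
    if use.sum() < 2:
        raise ValueError("need >= 2 informative bins for a log-log slope")
    x = np.log(est.midpoints[use])
    y = np.log(est.hazard[use])
    w = est.events[use].astype(float)
    wx = np.sum(w * x) / np.sum(w)
    wy = np.sum(w * y) / np.sum(w)
    slope = float(np.sum(w * (x - wx) * (y - wy)) / np.sum(w * (x - wx) ** 2))
    return slope, float(wy - slope * wx)


def expected_hazard(rates: MultistageRates, t) -> np.ndarray:
    """Power-law hazard k t^(r-1) implied by the rates (rare-event limit)."""
    t = np.asarray(t, dtype=float)
    return aggregate_k(rates) * t ** (rates.r - 1)
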