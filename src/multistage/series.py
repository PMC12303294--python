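"""The age-incidence series container shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

Gender = str  # "female", "male" or "both"


@dataclass(frozen=True)
class IncidenceSeries:
    """Age-specific incidence for one cancer x gender x population.

    Ages are integer *classes* (1, 2, 3, ...): consecutive relabellings of
    registry age groups with unit spacing on the log-time axis.  The
    original group labels (e.g. "0-14", "15-39") may be kept as metadata
    but are never used as numeric time.  Incidence is a rate per 100,000
    persons per unit time and is non-negative; zeros are allowed in the
    container and handled downstream (leading zeros by class renumbering,
    interior zeros by exclusion at fit time).
    """

    cancer: str
    gender: Gender
    age_class: Tuple[int, ...]
    incidence: Tuple[float, ...]
    population: str = ""
    age_labels: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        ages = tuple(int(a) for a in self.age_class)
        inc = tuple(float(x) for x in self.incidence)
        if len(ages) != len(inc):
            raise ValueError("age_class and incidence must have equal length")
        if len(ages) == 0:
            raise ValueError("series must contain at least one age class")
        if any(a2 <= a1 for a1, a2 in zip(ages, ages[1:])):
            raise ValueError(f"age classes must be strictly increasing: {ages}")
        if ages[0] < 1:
            raise ValueError(f"age classes must start at >= 1, got {ages[0]}")
        if any(x < 0 for x in inc):
            raise ValueError("incidence must be non-negative")
        if self.age_labels is not None and len(self.age_labels) != len(ages):
            raise ValueError("age_labels length must match age_class")
        object.__setattr__(self, "age_class", ages)
        object.__setattr__(self, "incidence", inc)

    def __len__(self) -> int:
        return len(self.age_class)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.age_class, dtype=float)

    @property
    def rate(self) -> np.ndarray:
        return np.asarray(self.incidence, dtype=float)

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.cancer, self.gender, self.population)

    def positive_mask(self) -> np.ndarray:
        """Classes usable on the log scale (incidence strictly positive)."""
        return self.rate > 0

    def with_incidence(self, incidence: Sequence[float]) -> "IncidenceSeries":
        return replace(self, incidence=tuple(float(x) for x in incidence))
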