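"""CSV readers/writers, age-class renumbering and run configuration.

Input is a flat table with columns ``cancer``, ``gender``, ``incidence``
and either ``age_class`` (integers) or ``age_group`` (registry labels in
file order); an optional ``population`` column separates registries.
Rows are grouped into one :class:`~multistage.series.IncidenceSeries`
per (cancer, gender, population).

Registry age groups have unequal widths, so they are renumbered to
consecutive integer classes with unit log-time spacing before fitting;
rescaling the time axis only shifts the intercept, never the slope, so
the step-count estimate is unaffected.  If the leading age group has
zero incidence in both genders it is dropped and the next group becomes
class 1 — structural zeros have no logarithm.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .fitting import FitResult, SelectionResult
from .models import CurvedParams, LinearParams
from .series import IncidenceSeries

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("cancer", "gender", "incidence")


@dataclass(frozen=True)
class RunConfig:
    """Tunable settings for a batch run; JSON-serialisable."""

    tie_tolerance: float = 0.005
    anchor_min: int = 3
    noise_sd: float = 0.05
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


class InputError(ValueError):
    """Malformed input table."""


def read_incidence_csv(
    path: Union[str, Path], tsv: bool = False
) -> List[IncidenceSeries]:
    """Read an incidence table into one series per (cancer, gender, population).

    Rows may arrive in any order; series are ordered by age class.  Age
    classes are taken from an ``age_class`` column when present,
    otherwise assigned 1..n in file order of the ``age_group`` labels.
    """
    df = pd.read_csv(path, sep="\t" if tsv else ",")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    if "age_class" not in df.columns and "age_group" not in df.columns:
        raise InputError(f"{path}: need an age_class or age_group column")
    if not pd.api.types.is_numeric_dtype(df["incidence"]):
        bad = df.loc[pd.to_numeric(df["incidence"], errors="coerce").isna()]
        raise InputError(
            f"{path}: non-numeric incidence values at rows {bad.index.tolist()}"
        )
    if "population" not in df.columns:
        df["population"] = ""
    else:
        # an absent registry label must not make groupby drop the rows
        df["population"] = df["population"].fillna("").astype(str)

    series: List[IncidenceSeries] = []
    for (cancer, gender, population), grp in df.groupby(
        ["cancer", "gender", "population"], sort=True
    ):
        if "age_class" in grp.columns:
            grp = grp.sort_values("age_class")
            ages = grp["age_class"].astype(int).tolist()
        else:
            # file order defines the class order for labelled groups
            ages = list(range(1, len(grp) + 1))
        age_key = grp["age_class"] if "age_class" in grp.columns else grp["age_group"]
        if age_key.duplicated().any():
            dup = age_key[age_key.duplicated()].tolist()
            raise InputError(
                f"{path}: duplicate age entries {dup} for "
                f"({cancer}, {gender}, {population})"
            )
        labels = (
            tuple(grp["age_group"].astype(str)) if "age_group" in grp.columns else None
        )
        series.append(
            IncidenceSeries(
                cancer=str(cancer),
                gender=str(gender),
                population=str(population),
                age_class=tuple(ages),
                incidence=tuple(grp["incidence"].astype(float)),
                age_labels=labels,
            )
        )
    return series


def assign_age_classes(
    group: Sequence[IncidenceSeries],
) -> List[IncidenceSeries]:
    """Apply the leading-zero rule and renumber classes 1, 2, 3, ...

    ``group`` holds the gender series of one cancer x population
    (typically female + male).  Leading age classes whose incidence is
    zero in *every* series of the group are dropped — the rule requires
    the zero in both genders — and the remaining classes are renumbered
    consecutively from 1.  A zero in only one gender is kept (it is
    excluded at fit time for that gender alone).  Idempotent.
    """
    if not group:
        raise InputError("empty series group")
    first = group[0]
    for s in group[1:]:
        if s.age_class != first.age_class:
            raise InputError(
                f"series in group must share age classes: "
                f"{s.key} vs {first.key}"
            )
    n = len(first)
    drop = 0
    while drop < n and all(s.incidence[drop] == 0 for s in group):
        drop += 1
    if drop == n:
        raise InputError(
            f"all age classes have zero incidence in every series of group "
            f"{[s.key for s in group]}"
        )
    if drop:
        logger.info(
            "dropping %d leading zero-incidence age class(es) for group %s",
            drop, [s.key for s in group],
        )
    out = []
    for s in group:
        out.append(
            replace(
                s,
                age_class=tuple(range(1, n - drop + 1)),
                incidence=s.incidence[drop:],
                age_labels=s.age_labels[drop:] if s.age_labels else None,
            )
        )
    return out


def _linear_row(key: Tuple[str, str, str], fit: FitResult) -> Dict:
    p: LinearParams = fit.params
    return {
        "cancer": key[0],
        "gender": key[1],
        "population": key[2],
        "intercept": p.intercept,
        "slope": p.slope,
        "r_squared": fit.r_squared,
    }


def _curved_row(key: Tuple[str, str, str], fit: FitResult) -> Dict:
    p: CurvedParams = fit.params
    import math

    k_p = math.exp(p.a0)
    return {
        "cancer": key[0],
        "gender": key[1],
        "population": key[2],
        "curvature": p.curvature,
        "a0": p.a0,
        "a1": p.a1,
        "a2": p.a2,
        "a3": p.a3,
        "r_squared": fit.r_squared,
        "k_p": k_p,
        "k_q": p.a2 * k_p,
    }


def write_results(
    results: Dict[Tuple[str, str, str], Union[FitResult, SelectionResult]],
    path: Union[str, Path],
    fmt: str = "csv",
) -> List[Path]:
    """Write fit results as CSV tables (linear and curved separately) or JSON.

    For ``fmt="csv"``, linear fits go to ``<stem>_linear.csv`` with
    columns (cancer, gender, population, intercept, slope, r_squared)
    and curved fits to ``<stem>_curved.csv`` with the four coefficients,
    R^2 and the implied k_p, k_q.  For ``fmt="json"`` the full results
    (all attempted fits, residuals, selection metadata) go to one file.
    Returns the paths written.
    """
    if not results:
        raise ValueError("no results to write")
    path = Path(path)

    def best(v) -> FitResult:
        return v.best if isinstance(v, SelectionResult) else v

    if fmt == "json":
        payload = {}
        for key, v in results.items():
            entry: Dict = {}
            fits = v.fits if isinstance(v, SelectionResult) else {best(v).model_kind: v}
            for kind, fit in fits.items():
                entry[kind] = {
                    "params": dataclasses.asdict(fit.params),
                    "r_squared": fit.r_squared,
                    "residuals": list(fit.residuals),
                    "anchor_size": fit.anchor_size,
                }
            if isinstance(v, SelectionResult):
                entry["chosen"] = v.chosen
                entry["tie_tolerance"] = v.tie_tolerance
                entry["failures"] = v.failures
            payload["|".join(key)] = entry
        path.write_text(json.dumps(payload, indent=2))
        return [path]

    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")
    linear_rows, curved_rows = [], []
    for key, v in results.items():
        fit = best(v)
        if fit.model_kind == "linear":
            linear_rows.append(_linear_row(key, fit))
        else:
            curved_rows.append(_curved_row(key, fit))
    written = []
    if linear_rows:
        p = path.with_name(path.stem + "_linear.csv")
        pd.DataFrame(linear_rows).to_csv(p, index=False)
        written.append(p)
    if curved_rows:
        p = path.with_name(path.stem + "_curved.csv")
        pd.DataFrame(curved_rows).to_csv(p, index=False)
        written.append(p)
    return written


def write_series_csv(
    series: Iterable[IncidenceSeries], path: Union[str, Path]
) -> Path:
    """Write series in the same dialect :func:`read_incidence_csv` reads."""
    rows = []
    for s in series:
        for i, (a, inc) in enumerate(zip(s.age_class, s.incidence)):
            row = {
                "cancer": s.cancer,
                "gender": s.gender,
                "population": s.population,
                "age_class": a,
                "incidence": inc,
            }
            if s.age_labels:
                row["age_group"] = s.age_labels[i]
            rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
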