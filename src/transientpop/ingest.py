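"""Reading, cleaning and five-year binning of single-year demographic tables.

Tables hold age-specific female population sizes, deaths and births by
maternal age for one country-year, on single-year ages 0..84 plus an open
"85+" class (86 cells).  Cleaning follows two rules: country-years whose
single-year death vector contains a run of five or more consecutive exact
zeros are excluded (such runs suggest inaccurate collection or impractically
small populations), and female births are estimated from total births via a
constant sex ratio at birth.  Counts are then aggregated into 18 five-year
bins (0-4, 5-9, ..., 80-84, 85+) for matrix construction, keeping the
age-0 versus ages-1-4 split of the first bin, which the survival model
weights separately because infant mortality far exceeds child mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

#: number of single-year age cells: ages 0..84 plus the open "85+" class
N_SINGLE_AGES = 86
#: number of five-year bins: 0-4 ... 80-84 plus 85+
N_BINS = 18
#: literal token used for the open age class in tables
OPEN_AGE_LABEL = "85+"
#: default sex ratio at birth (male births per female birth)
DEFAULT_SRB = 1.05
#: default exclusion threshold: runs of this many consecutive zero deaths
DEFAULT_ZERO_RUN = 5

BIN_LABELS = tuple(f"{5 * i}-{5 * i + 4}" for i in range(17)) + (OPEN_AGE_LABEL,)


@dataclass
class AgeSeries:
    """Single-year demographic counts for one country-year.

    ``births_by_maternal_age`` holds total (both-sex) births attributed to
    the mother's single-year age; ``total_births`` is its sum.
    """

    country: str
    year: int
    population: np.ndarray
    deaths: np.ndarray
    births_by_maternal_age: np.ndarray
    total_births: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=float)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.births_by_maternal_age = np.asarray(
            self.births_by_maternal_age, dtype=float
        )
        for name in ("population", "deaths", "births_by_maternal_age"):
            vec = getattr(self, name)
            if vec.shape != (N_SINGLE_AGES,):
                raise ValidationError(
                    f"{self.country} {self.year}: {name} must have length "
                    f"{N_SINGLE_AGES} (ages 0..84 plus {OPEN_AGE_LABEL}), "
                    f"got {vec.shape}"
                )
            if np.any(vec < 0):
                raise ValidationError(
                    f"{self.country} {self.year}: negative values in {name}"
                )
        implied = float(self.births_by_maternal_age.sum())
        if self.total_births is None:
            self.total_births = implied
        elif abs(self.total_births - implied) > 1e-9 * max(1.0, implied):
            raise ValidationError(
                f"{self.country} {self.year}: total_births "
                f"{self.total_births} inconsistent with maternal-age sum "
                f"{implied}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.country, self.year)


@dataclass
class BinnedDemography:
    """Counts aggregated into the 18 five-year bins.

    ``female_births`` is already converted from total births via the sex
    ratio at birth.  The age-0 / ages-1-4 split of the first bin is kept so
    the projection-matrix builder can weight infant and child survival
    separately.
    """

    country: str
    year: int
    population: np.ndarray
    deaths: np.ndarray
    female_births: np.ndarray
    infant_population: float
    infant_deaths: float
    child_population: float
    child_deaths: float

    def __post_init__(self) -> None:
        for name in ("population", "deaths", "female_births"):
            vec = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, vec)
            if vec.shape != (N_BINS,):
                raise ValidationError(
                    f"{self.country} {self.year}: {name} must have "
                    f"{N_BINS} bins, got {vec.shape}"
                )
            if np.any(vec < 0):
                raise ValidationError(
                    f"{self.country} {self.year}: negative values in {name}"
                )

    @property
    def key(self) -> tuple[str, int]:
        return (self.country, self.year)


def _parse_age(token: str, line_no: int) -> int:
    token = str(token).strip()
    if token == OPEN_AGE_LABEL:
        return N_SINGLE_AGES - 1
    try:
        age = int(token)
    except ValueError as exc:
        raise ParseError(f"line {line_no}: unparseable age {token!r}") from exc
    if not 0 <= age <= 84:
        raise ParseError(
            f"line {line_no}: age {age} outside 0..84 "
            f"(use {OPEN_AGE_LABEL!r} for the open class)"
        )
    return age


def read_demography_table(path: str | Path) -> list[AgeSeries]:
    """Read a delimited demographic table into one AgeSeries per country-year.

    The file must contain columns country, year, age, population, deaths and
    births, one row per single-year age, with the open class labelled "85+".
    Country-years missing the open class, missing ages, or containing
    negative counts are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype={"age": str}, float_precision="round_trip")
    required = {"country", "year", "age", "population", "deaths", "births"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    # line numbers for error messages: header is line 1
    frame = frame.reset_index(drop=True)
    frame["line_no"] = frame.index + 2
    out: list[AgeSeries] = []
    for (country, year), group in frame.groupby(["country", "year"], sort=True):
        pop = np.zeros(N_SINGLE_AGES)
        dth = np.zeros(N_SINGLE_AGES)
        brt = np.zeros(N_SINGLE_AGES)
        seen = np.zeros(N_SINGLE_AGES, dtype=bool)
        for row in group.itertuples(index=False):
            line = row.line_no
            idx = _parse_age(row.age, line)
            if seen[idx]:
                raise ParseError(
                    f"line {line}: duplicate age {row.age!r} for "
                    f"{country} {year}"
                )
            seen[idx] = True
            for col, vec in (("population", pop), ("deaths", dth), ("births", brt)):
                value = float(getattr(row, col))
                if not np.isfinite(value):
                    raise ParseError(
                        f"line {line}: non-finite {col} for {country} {year}"
                    )
                if value < 0:
                    raise ValidationError(
                        f"line {line}: negative {col} for {country} {year}"
                    )
                vec[idx] = value
        if not seen[-1]:
            raise ValidationError(
                f"{country} {year}: missing the open {OPEN_AGE_LABEL!r} row"
            )
        if not seen.all():
            absent = np.flatnonzero(~seen)
            raise ValidationError(
                f"{country} {year}: missing single-year ages {absent.tolist()}"
            )
        out.append(
            AgeSeries(
                country=str(country),
                year=int(year),
                population=pop,
                deaths=dth,
                births_by_maternal_age=brt,
            )
        )
    return out


def longest_zero_run(values: np.ndarray) -> int:
    """Length of the longest run of consecutive exact zeros in a vector."""
    longest = run = 0
    for v in np.asarray(values).ravel():
        if v == 0:
            run += 1
            longest = max(longest, run)
        else:
            run = 0
    return longest


def zero_death_filter(series: AgeSeries, run_length: int = DEFAULT_ZERO_RUN) -> bool:
    """Return True (keep) unless the single-year deaths vector contains
    ``run_length`` or more consecutive exact zeros.

    The run is evaluated over the full vector including the open 85+ class.
    """
    if run_length < 1:
        raise ConfigurationError("run_length must be >= 1")
    return longest_zero_run(series.deaths) < run_length


def estimate_female_births(total_births, sex_ratio_at_birth: float = DEFAULT_SRB):
    """Convert total births to female births via the sex ratio at birth.

    With ``r`` male births per female birth, a fraction 1/(1+r) of all
    births is female.  Accepts scalars or arrays.
    """
    if not np.isfinite(sex_ratio_at_birth) or sex_ratio_at_birth <= 0:
        raise ConfigurationError(
            f"sex ratio at birth must be a positive finite number, "
            f"got {sex_ratio_at_birth}"
        )
    return np.asarray(total_births, dtype=float) / (1.0 + sex_ratio_at_birth)


def bin_to_five_year(
    series: AgeSeries, sex_ratio_at_birth: float = DEFAULT_SRB
) -> BinnedDemography:
    """Aggregate single-year counts into the 18 five-year bins.

    Populations and deaths are summed within bins; births are converted to
    female births (sex ratio at birth) and summed by maternal-age bin.  The
    age-0 versus ages-1-4 split of the first bin is retained.
    """
    def fold(vec: np.ndarray) -> np.ndarray:
        closed = vec[:85].reshape(17, 5).sum(axis=1)
        return np.concatenate([closed, vec[85:]])

    female = estimate_female_births(series.births_by_maternal_age, sex_ratio_at_birth)
    return BinnedDemography(
        country=series.country,
        year=series.year,
        population=fold(series.population),
        deaths=fold(series.deaths),
        female_births=fold(female),
        infant_population=float(series.population[0]),
        infant_deaths=float(series.deaths[0]),
        child_population=float(series.population[1:5].sum()),
        child_deaths=float(series.deaths[1:5].sum()),
    )


@dataclass
class CleaningRecord:
    """One excluded country-year and the rule that triggered exclusion."""

    country: str
    year: int
    rule: str
    detail: str


def apply_filters(
    series: Iterable[AgeSeries], run_length: int = DEFAULT_ZERO_RUN
) -> tuple[list[AgeSeries], list[CleaningRecord]]:
    """Partition country-years into retained series and an exclusion audit."""
    kept: list[AgeSeries] = []
    audit: list[CleaningRecord] = []
    for s in series:
        if zero_death_filter(s, run_length):
            kept.append(s)
        else:
            audit.append(
                CleaningRecord(
                    country=s.country,
                    year=s.year,
                    rule="zero_death_run",
                    detail=(
                        f"longest run of consecutive zero deaths = "
                        f"{longest_zero_run(s.deaths)} >= {run_length}"
                    ),
                )
            )
    return kept, audit


def write_cleaning_log(audit: Sequence[CleaningRecord], path: str | Path) -> None:
    """Write the exclusion audit as a CSV file."""
    frame = pd.DataFrame(
        [(r.country, r.year, r.rule, r.detail) for r in audit],
        columns=["country", "year", "rule", "detail"],
    )
    frame.to_csv(path, index=False)
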