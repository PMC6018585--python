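"""Synthetic Eurostat-shaped demographic tables with known vital rates.

Generates single-year tables of female population, deaths and births by
maternal age for a panel of countries and years, in the same shape as the
real extraction the pipeline targets (ages 0..84 plus an open "85+" class).
Mortality follows a Makeham-Gompertz law a + b*exp(c*age) with an infant
excess at age 0; fertility is a Gaussian hump over a reproductive window,
scaled to a configurable lifetime total.  Because the underlying rates are
known, every downstream stage (binning, matrix construction, transient
indices) can be tested for exact rate recovery.

Deaths are emitted per single-year age as population * rate / 5 per year
(the rates are per five-year step), so that the downstream estimator
5 * deaths / population recovers the configured rate exactly when noise is
off.  Counts are real-valued by default; Poisson sampling is opt-in, which
keeps estimator correctness separate from sampling noise.  Age pyramids
default to the stationary structure implied by the mortality schedule, with
a multiplicative "boom" perturbation on a configurable cohort band — the
transient indices are only informative away from the stable structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SeriesLookupError
from .ingest import (
    DEFAULT_SRB,
    N_SINGLE_AGES,
    OPEN_AGE_LABEL,
    AgeSeries,
)

AGES = np.arange(N_SINGLE_AGES)  # 0..85; 85 indexes the open class


@dataclass(frozen=True)
class VitalRateSchedule:
    """Ground-truth per-age vital rates (per five-year step).

    ``death_rate[a]`` is the probability of dying over one five-year
    projection step for an individual of single-year age ``a``;
    ``fertility_rate[a]`` the expected daughters per female per step.
    """

    death_rate: np.ndarray
    fertility_rate: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.death_rate, dtype=float)
        f = np.asarray(self.fertility_rate, dtype=float)
        object.__setattr__(self, "death_rate", d)
        object.__setattr__(self, "fertility_rate", f)
        if d.shape != (N_SINGLE_AGES,) or f.shape != (N_SINGLE_AGES,):
            raise ConfigurationError("schedules must cover ages 0..85")
        if np.any((d < 0) | (d > 1)):
            raise ConfigurationError("death rates must lie in [0, 1]")
        if np.any(f < 0):
            raise ConfigurationError("fertility rates must be nonnegative")


@dataclass(frozen=True)
class Anomaly:
    """A deliberate data defect injected into one country-year.

    Either a run of single-year death counts set to exactly zero
    (``zero_run_start``/``zero_run_length``) or a floor applied to all
    population cells (``population_floor``).
    """

    country: str
    year: int
    zero_run_start: int | None = None
    zero_run_length: int | None = None
    population_floor: float | None = None


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic demographic panel.

    Mortality: per-five-year-step death rate a + b*exp(c*age), clamped to
    [0, 1], with age 0 multiplied by ``infant_excess``.  Defaults give a
    low-mortality regime with e.g. rate(0) ~ 0.8%, rate(80) ~ 6%.
    Fertility: Gaussian hump centred on ``fertility_peak_age`` with sd
    ``fertility_width`` years, zero outside ``reproductive_window``,
    normalised so the sum of per-step daughter rates over all single-year
    ages equals ``tfr_scale``.  A cohort spends one year (one-fifth of a
    step) at each single-year age, so lifetime daughters per female is
    about ``tfr_scale / 5``: the default 4.25 corresponds to ~0.85
    daughters (total fertility rate ~1.74), slightly below replacement as
    in late-20th-century Europe, giving lambda_1 just under 1.
    ``boom_amplitude`` is the maximum relative size of the multiplicative
    cohort perturbation applied to the stationary pyramid (drawn per
    country-year from the seeded stream).  ``rate_variation`` is the
    half-width of the log-uniform factor applied to the whole mortality
    and fertility schedules per country-year, emulating cross-country and
    temporal differences in vital rates; the realised schedule of any
    country-year is reproducible via :func:`schedule_for`.
    """

    n_countries: int = 3
    years: tuple[int, int] = (2000, 2009)
    base_population: float = 100_000.0
    makeham_a: float = 0.001
    gompertz_b: float = 2e-5
    gompertz_c: float = 0.1
    infant_excess: float = 8.0
    fertility_peak_age: float = 28.0
    fertility_width: float = 6.0
    tfr_scale: float = 4.25
    reproductive_window: tuple[int, int] = (12, 55)
    sex_ratio_at_birth: float = DEFAULT_SRB
    seed: int = 0
    poisson_noise: bool = False
    boom_ages: tuple[int, int] = (18, 37)
    boom_amplitude: float = 0.15
    rate_variation: float = 0.10
    anomaly_spec: tuple[Anomaly, ...] = field(default_factory=tuple)

    def country_names(self) -> list[str]:
        return [f"C{i:02d}" for i in range(self.n_countries)]

    def year_range(self) -> range:
        lo, hi = self.years
        return range(lo, hi + 1)


def _check_finite(config: SyntheticConfig, names: Sequence[str]) -> None:
    for name in names:
        value = getattr(config, name)
        if not np.isfinite(value):
            raise ConfigurationError(f"{name} must be finite, got {value}")


def make_mortality_schedule(config: SyntheticConfig) -> np.ndarray:
    """Per-age death rates (per five-year step) under the Makeham-Gompertz
    law, with the infant excess applied at age 0 and clamping to [0, 1]."""
    _check_finite(
        config, ["makeham_a", "gompertz_b", "gompertz_c", "infant_excess"]
    )
    if config.gompertz_b < 0:
        raise ConfigurationError("gompertz_b must be >= 0")
    if config.infant_excess < 1:
        raise ConfigurationError("infant_excess must be >= 1")
    rate = config.makeham_a + config.gompertz_b * np.exp(config.gompertz_c * AGES)
    rate[0] *= config.infant_excess
    return np.clip(rate, 0.0, 1.0)


def make_fertility_schedule(config: SyntheticConfig) -> np.ndarray:
    """Per-age daughter rates (per five-year step): a Gaussian hump centred
    on the peak age, zero outside the reproductive window, scaled so the
    lifetime sum equals ``tfr_scale``."""
    _check_finite(config, ["fertility_peak_age", "fertility_width", "tfr_scale"])
    if config.fertility_width <= 0:
        raise ConfigurationError("fertility_width must be > 0")
    if config.tfr_scale < 0:
        raise ConfigurationError("tfr_scale must be >= 0")
    lo, hi = config.reproductive_window
    kernel = np.exp(
        -0.5 * ((AGES - config.fertility_peak_age) / config.fertility_width) ** 2
    )
    kernel[(AGES < lo) | (AGES > hi)] = 0.0
    total = kernel.sum()
    if total == 0 or config.tfr_scale == 0:
        return np.zeros_like(kernel)
    return kernel * (config.tfr_scale / total)


def make_schedule(config: SyntheticConfig) -> VitalRateSchedule:
    return VitalRateSchedule(
        death_rate=make_mortality_schedule(config),
        fertility_rate=make_fertility_schedule(config),
    )


def _stationary_pyramid(config: SyntheticConfig, death_rate: np.ndarray) -> np.ndarray:
    """Stationary age structure under the per-year mortality d/5: each age
    class is the previous one thinned by a year of survival; the open 85+
    class holds the stationary balance inflow / per-year death rate."""
    annual = death_rate / 5.0
    pop = np.empty(N_SINGLE_AGES)
    pop[0] = config.base_population
    for a in range(1, N_SINGLE_AGES - 1):
        pop[a] = pop[a - 1] * max(0.0, 1.0 - annual[a - 1])
    inflow = pop[-2] * max(0.0, 1.0 - annual[-2])
    pop[-1] = inflow / max(annual[-1], 0.02)
    return pop


def _country_year_rng(config: SyntheticConfig, country_index: int, year: int):
    """Independent, reproducible random stream for one country-year."""
    ss = np.random.SeedSequence([abs(int(config.seed)), country_index, int(year)])
    return np.random.default_rng(ss)


def _draw_rate_factors(config: SyntheticConfig, rng) -> tuple[float, float, float]:
    """The three per-country-year draws, in a fixed order: log-uniform
    mortality factor, log-uniform fertility factor, boom amplitude."""
    u_mort = rng.uniform(-config.rate_variation, config.rate_variation)
    u_fert = rng.uniform(-config.rate_variation, config.rate_variation)
    amp = rng.uniform(-config.boom_amplitude, config.boom_amplitude)
    return float(np.exp(u_mort)), float(np.exp(u_fert)), amp


def schedule_for(config: SyntheticConfig, country: str, year: int) -> VitalRateSchedule:
    """Realised vital-rate schedule of one country-year.

    Reproduces, without simulating, the schedule that
    :func:`simulate_country_series` uses for that country-year: the base
    Makeham-Gompertz and Gaussian-fertility schedules scaled by the
    country-year's seeded log-uniform factors.
    """
    ci = config.country_names().index(country)
    rng = _country_year_rng(config, ci, year)
    f_mort, f_fert, _ = _draw_rate_factors(config, rng)
    base = make_schedule(config)
    return VitalRateSchedule(
        death_rate=np.clip(base.death_rate * f_mort, 0.0, 1.0),
        fertility_rate=base.fertility_rate * f_fert,
    )


def simulate_country_series(config: SyntheticConfig) -> list[AgeSeries]:
    """Generate the full synthetic panel, one AgeSeries per country-year.

    Deterministic given the seed.  Each country-year gets its own scaled
    vital-rate schedule (see :func:`schedule_for`), a stationary age
    pyramid under that mortality, and a multiplicative cohort boom/bust
    on the configured age band.  Deaths and female births are
    population * rate / 5 per year; the births column holds both-sex
    births (female * (1 + sex ratio at birth)), matching the raw-table
    convention in which births are not sex-separated.
    """
    make_schedule(config)  # validate base parameters once
    lo, hi = config.boom_ages
    boom_band = (AGES >= lo) & (AGES <= hi)

    out: list[AgeSeries] = []
    for ci, country in enumerate(config.country_names()):
        for year in config.year_range():
            rng = _country_year_rng(config, ci, year)
            f_mort, f_fert, amp = _draw_rate_factors(config, rng)
            schedule = schedule_for(config, country, year)
            pop = _stationary_pyramid(config, schedule.death_rate)
            pop[boom_band] *= 1.0 + amp
            deaths = pop * schedule.death_rate / 5.0
            daughters = pop * schedule.fertility_rate / 5.0
            if config.poisson_noise:
                deaths = rng.poisson(deaths).astype(float)
                daughters = rng.poisson(daughters).astype(float)
            births = daughters * (1.0 + config.sex_ratio_at_birth)
            out.append(
                AgeSeries(
                    country=country,
                    year=year,
                    population=pop,
                    deaths=deaths,
                    births_by_maternal_age=births,
                )
            )
    return inject_anomalies(out, config.anomaly_spec)


def inject_anomalies(
    series: list[AgeSeries], anomaly_spec: Sequence[Anomaly]
) -> list[AgeSeries]:
    """Apply the requested defects, leaving all other cells untouched."""
    if not anomaly_spec:
        return series
    index = {s.key: i for i, s in enumerate(series)}
    out = list(series)
    for spec in anomaly_spec:
        key = (spec.country, spec.year)
        if key not in index:
            raise SeriesLookupError(
                f"anomaly references unknown country-year {key}"
            )
        i = index[key]
        s = out[i]
        deaths = s.deaths.copy()
        pop = s.population.copy()
        if spec.zero_run_length is not None:
            start = spec.zero_run_start or 0
            deaths[start : start + spec.zero_run_length] = 0.0
        if spec.population_floor is not None:
            pop = np.minimum(pop, spec.population_floor)
        out[i] = AgeSeries(
            country=s.country,
            year=s.year,
            population=pop,
            deaths=deaths,
            births_by_maternal_age=s.births_by_maternal_age.copy(),
        )
    return out


def expected_bin_rates(
    series: AgeSeries, schedule: VitalRateSchedule
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth per-bin death and daughter rates for one country-year.

    The crude bin estimator 5 * deaths / population recovers the
    population-weighted mean of the per-age rates within each bin; this
    helper computes those means from the schedule and the series' actual
    age pyramid, for exact round-trip assertions.
    Returns (death_rate_per_bin, daughter_rate_per_bin), both length 18.
    """
    def weighted(rate: np.ndarray) -> np.ndarray:
        num = series.population * rate
        closed_n = num[:85].reshape(17, 5).sum(axis=1)
        closed_d = series.population[:85].reshape(17, 5).sum(axis=1)
        out = np.empty(18)
        out[:17] = closed_n / closed_d
        out[17] = num[85] / series.population[85]
        return out

    return weighted(schedule.death_rate), weighted(schedule.fertility_rate)


def write_demography_table(series: Sequence[AgeSeries], path: str | Path) -> None:
    """Write the panel as a UTF-8 CSV: country, year, age, population,
    deaths, births; ages 0..84 plus the literal "85+"."""
    age_labels = [str(a) for a in range(85)] + [OPEN_AGE_LABEL]
    rows = []
    for s in series:
        for idx, label in enumerate(age_labels):
            rows.append(
                (
                    s.country,
                    s.year,
                    label,
                    repr(float(s.population[idx])),
                    repr(float(s.deaths[idx])),
                    repr(float(s.births_by_maternal_age[idx])),
                )
            )
    frame = pd.DataFrame(
        rows, columns=["country", "year", "age", "population", "deaths", "births"]
    )
    frame.to_csv(path, index=False)
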