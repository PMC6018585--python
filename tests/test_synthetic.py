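"""Synthetic-data generator: schedule shapes, determinism, rate recovery."""

import dataclasses

import numpy as np
import pytest

from transientpop import (
    Anomaly,
    ConfigurationError,
    SyntheticConfig,
    bin_to_five_year,
    build_ppm,
    inject_anomalies,
    make_fertility_schedule,
    make_mortality_schedule,
    simulate_country_series,
    zero_death_filter,
)
from transientpop.errors import SeriesLookupError
from transientpop.synthetic import expected_bin_rates, schedule_for


class TestMortalitySchedule:
    def test_zero_mortality_limit(self):
        cfg = SyntheticConfig(makeham_a=0.0, gompertz_b=0.0, infant_excess=1.0)
        assert np.all(make_mortality_schedule(cfg) == 0.0)

    def test_clamping_at_one(self):
        cfg = SyntheticConfig(makeham_a=1.0)
        assert np.all(make_mortality_schedule(cfg) == 1.0)

    def test_gompertz_increase_matches_closed_form(self):
        cfg = SyntheticConfig(
            makeham_a=0.001, gompertz_b=2e-5, gompertz_c=0.1, infant_excess=1.0
        )
        rates = make_mortality_schedule(cfg)
        expected = lambda a: 0.001 + 2e-5 * np.exp(0.1 * a)
        for age in (20, 40, 80):
            assert rates[age] == pytest.approx(expected(age), rel=1e-12)
        assert rates[80] > rates[40] > rates[20]

    def test_monotone_after_30(self, default_config):
        rates = make_mortality_schedule(default_config)
        assert np.all(np.diff(rates[30:]) >= 0)

    def test_nonfinite_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            make_mortality_schedule(SyntheticConfig(makeham_a=np.nan))


class TestFertilitySchedule:
    def test_zero_scale(self):
        cfg = SyntheticConfig(tfr_scale=0.0)
        assert np.all(make_fertility_schedule(cfg) == 0.0)

    def test_peak_is_mode(self):
        cfg = SyntheticConfig(fertility_peak_age=28, fertility_width=6)
        rates = make_fertility_schedule(cfg)
        assert np.argmax(rates) == 28

    def test_normalisation(self):
        cfg = SyntheticConfig(tfr_scale=1.0)
        assert make_fertility_schedule(cfg).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_outside_window(self, default_config):
        rates = make_fertility_schedule(default_config)
        lo, hi = default_config.reproductive_window
        ages = np.arange(rates.size)
        assert np.all(rates[(ages < lo) | (ages > hi)] == 0.0)

    def test_negative_scale_rejected(self):
        with pytest.raises(ConfigurationError):
            make_fertility_schedule(SyntheticConfig(tfr_scale=-1.0))


class TestSimulation:
    def test_determinism(self, default_config, small_panel):
        again = simulate_country_series(dataclasses.replace(default_config))
        assert len(again) == len(small_panel)
        for a, b in zip(again, small_panel):
            assert a.key == b.key
            np.testing.assert_array_equal(a.population, b.population)
            np.testing.assert_array_equal(a.deaths, b.deaths)
            np.testing.assert_array_equal(
                a.births_by_maternal_age, b.births_by_maternal_age
            )

    def test_counts_nonnegative(self, small_panel):
        for s in small_panel:
            assert np.all(s.population >= 0)
            assert np.all(s.deaths >= 0)
            assert np.all(s.births_by_maternal_age >= 0)

    def test_noiseless_round_trip_recovers_rates(self, default_config, small_panel):
        """The crude estimator 5*deaths/pop on binned counts must recover
        the population-weighted per-bin schedule rates exactly."""
        for s in small_panel[:5]:
            schedule = schedule_for(default_config, s.country, s.year)
            death_bin, daughter_bin = expected_bin_rates(s, schedule)
            ppm = build_ppm(bin_to_five_year(s, default_config.sex_ratio_at_birth))
            # subdiagonal bins 5-9 ... 80-84 carry plain bin survival
            np.testing.assert_allclose(
                ppm.survivals[1:], 1.0 - death_bin[1:17], rtol=1e-9, atol=1e-12
            )
            assert ppm.stasis == pytest.approx(1.0 - death_bin[17], rel=1e-9)
            # fertility: crude daughter rate times the survival discounts
            s04 = ppm.survivals[0]
            maternal = np.concatenate([ppm.survivals, [ppm.stasis]])
            expected = daughter_bin * np.sqrt(maternal) * np.sqrt(s04)
            np.testing.assert_allclose(
                ppm.fertilities, expected, rtol=1e-9, atol=1e-12
            )

    def test_poisson_recovery_within_three_se(self):
        """With Poisson sampling and ~1e5 persons per bin, crude death and
        daughter rates fall within 3 standard errors of the truth."""
        cfg = SyntheticConfig(
            n_countries=1,
            years=(2000, 2000),
            base_population=20_000.0,  # ~1e5 per five-year bin
            poisson_noise=True,
            boom_amplitude=0.0,
            seed=0,
        )
        s = simulate_country_series(cfg)[0]
        death_bin, daughter_bin = expected_bin_rates(
            s, schedule_for(cfg, s.country, s.year)
        )
        binned = bin_to_five_year(s, cfg.sex_ratio_at_birth)
        for truth, count in (
            (death_bin, binned.deaths),
            (daughter_bin, binned.female_births),
        ):
            estimate = 5.0 * count / binned.population
            # Poisson count with mean N*m/5 -> Var(5*C/N) = 5*m/N
            se = np.sqrt(5.0 * truth / binned.population)
            assert np.all(np.abs(estimate - truth) <= 3.0 * se + 1e-12)


class TestAnomalies:
    def test_zero_run_injected_exactly(self, small_panel):
        spec = [Anomaly("C00", 2003, zero_run_start=20, zero_run_length=5)]
        modified = inject_anomalies(small_panel, spec)
        target = next(s for s in modified if s.key == ("C00", 2003))
        original = next(s for s in small_panel if s.key == ("C00", 2003))
        assert np.all(target.deaths[20:25] == 0.0)
        mask = np.ones(86, dtype=bool)
        mask[20:25] = False
        np.testing.assert_array_equal(target.deaths[mask], original.deaths[mask])
        np.testing.assert_array_equal(target.population, original.population)

    def test_empty_spec_is_identity(self, small_panel):
        assert inject_anomalies(small_panel, []) is small_panel

    def test_run_of_four_survives_filter(self, small_panel):
        spec = [Anomaly("C00", 2004, zero_run_start=30, zero_run_length=4)]
        target = next(
            s
            for s in inject_anomalies(small_panel, spec)
            if s.key == ("C00", 2004)
        )
        assert zero_death_filter(target, run_length=5)

    def test_unknown_country_year_raises(self, small_panel):
        with pytest.raises(SeriesLookupError):
            inject_anomalies(
                small_panel, [Anomaly("XX", 1900, zero_run_length=5)]
            )

    def test_population_floor(self, small_panel):
        spec = [Anomaly("C01", 2005, population_floor=10.0)]
        target = next(
            s
            for s in inject_anomalies(small_panel, spec)
            if s.key == ("C01", 2005)
        )
        assert np.all(target.population <= 10.0)
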