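import dataclasses

import numpy as np
import pytest

from transientpop import (
    SyntheticConfig,
    bin_to_five_year,
    build_ppm,
    simulate_country_series,
)


def random_ppm_ensemble(n, seed0=0):
    """n projection matrices from synthetic panels with varied fertility,
    mortality and cohort-perturbation settings (deterministic)."""
    mats = []
    for k in range(n):
        cfg = SyntheticConfig(
            n_countries=1,
            years=(2000, 2000),
            seed=seed0 + k,
            tfr_scale=3.4 + 1.8 * (k % 10) / 9.0,
            gompertz_b=1e-5 * (1 + k % 7),
            boom_amplitude=0.25,
        )
        series = simulate_country_series(cfg)[0]
        mats.append(build_ppm(bin_to_five_year(series)))
    return mats


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def small_panel(default_config):
    return simulate_country_series(default_config)


@pytest.fixture(scope="session")
def sample_ppm(small_panel):
    return build_ppm(bin_to_five_year(small_panel[0]))


@pytest.fixture(scope="session")
def ppm_ensemble():
    return random_ppm_ensemble(100)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
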