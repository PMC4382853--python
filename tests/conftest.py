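import logging

import numpy as np
import pytest
from hypothesis import settings

from covbench import synthetic as syn

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

# Silence the (expected) clip/cap warnings during noisy-pipeline tests.
logging.getLogger("covbench").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_geo():
    return syn.generate_geography(3, 12, 2, seed=11)


@pytest.fixture(scope="session")
def small_scenario():
    """Four indicators (one launched mid-period) over a short window."""
    return syn.Scenario(indicators=(
        syn.IndicatorSpec("itn", "vertical", beta0=-10.2, trend=0.02,
                          ind_effect=13.0, launch_year=1999, floor_year=1997,
                          ramp_mid=2004),
        syn.IndicatorSpec("bcg", "routine", beta0=1.0, trend=0.015,
                          ind_effect=0.5, routine_level=0.88),
        syn.IndicatorSpec("anc4", "routine", beta0=0.8, trend=-0.07,
                          ind_effect=0.5, routine_level=0.60, slope_sd=0.04,
                          convergence=0.12),
        syn.IndicatorSpec("ebf", "routine", beta0=-1.8, trend=0.18,
                          ind_effect=0.5, routine_level=0.40),
    ))


@pytest.fixture(scope="session")
def small_truth(small_geo, small_scenario):
    return syn.generate_truth(small_geo, small_scenario.years,
                              small_scenario, seed=5)


@pytest.fixture(scope="session")
def small_plan(small_scenario):
    return syn.default_survey_plan(small_scenario)


@pytest.fixture(scope="session")
def small_pop(small_geo):
    return syn.generate_population(small_geo, [1990, 2000, 2010],
                                   base=1_000_000, growth=0.025, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
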