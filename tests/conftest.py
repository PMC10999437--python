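"""Shared fixtures: presets, generated weather, chamber and survey data."""

import numpy as np
import pytest

import philaenus as ph


@pytest.fixture(scope="session")
def calibrated():
    return ph.load_preset("calibrated")


@pytest.fixture(scope="session")
def parameterized():
    return ph.load_preset("parameterized")


@pytest.fixture(scope="session")
def age_dist():
    return ph.default_age_distribution()


@pytest.fixture(scope="session")
def diapause_params():
    return ph.default_diapause()


@pytest.fixture(scope="session")
def med_series():
    """One Mediterranean-preset hourly year, fixed seed."""
    return ph.generate_temperature_series(ph.MEDITERRANEAN, days=365)


@pytest.fixture(scope="session")
def const18_series():
    return ph.TemperatureSeries.from_daily(np.full(250, 18.0))


@pytest.fixture(scope="session")
def chamber_analytic(parameterized, age_dist):
    """Noiseless (infinite-cohort) chamber experiment from the chamber preset."""
    return ph.generate_chamber_experiment(parameterized, age_dist, analytic=True)


@pytest.fixture(scope="session")
def field_surveys(calibrated, age_dist, diapause_params):
    """Four noisy site-year surveys generated from the field preset."""
    return ph.generate_field_survey(calibrated, age_dist, diapause_params, seed=1)
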