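"""Temperature-driven phenology model of the meadow spittlebug.

A physiologically-based, stage-structured simulator of *Philaenus
spumarius* preimaginal phenology: Brière development-rate functions,
degree-day egg-diapause termination, a Beta-distributed initial egg age
and an age-transport (Kolmogorov) forward solver, together with the
chamber parameterization and two-step field calibration procedures and
synthetic-data generators emulating the underlying study designs.
"""

from __future__ import annotations

from .calibrate import (
    DiapauseGrid,
    FieldSurvey,
    calibrate_diapause,
    calibrate_rates,
)
from .characteristics import (
    entry_cdf_constant,
    entry_times_constant,
    entry_times_series,
)
from .diapause import DiapauseParams, degree_days, diapause_termination_day
from .evaluate import evaluate_fit
from .kolmogorov import (
    AgeDistribution,
    EmergenceTrajectory,
    PopulationState,
    cumulative_emergence_at,
    initialize,
    simulate,
    step,
)
from .parameterize import (
    ChamberDataset,
    GammaFit,
    fit_development_params,
    fit_gamma_emergence,
)
from .rates import (
    BriereParams,
    StageParamSet,
    briere_optimum,
    briere_rate,
    load_param_file,
    load_preset,
    scale_from_max,
)
from .synthetic import (
    MEDITERRANEAN,
    WeatherSpec,
    generate_chamber_experiment,
    generate_field_survey,
    generate_temperature_series,
)
from .temperature import TemperatureSeries

__version__ = "0.1.0"


def default_age_distribution() -> AgeDistribution:
    """Bundled initial egg-age distribution (Beta(5.67, 1.05))."""
    from .rates import _load_preset_file

    d = _load_preset_file()["age_distribution"]
    return AgeDistribution(float(d["alpha"]), float(d["beta"]))


def default_diapause() -> DiapauseParams:
    """Bundled field-calibrated diapause thresholds (6.5 °C, 120 DD)."""
    from .rates import _load_preset_file

    d = _load_preset_file()["diapause"]
    return DiapauseParams(t_e=float(d["t_e"]), dd_e=float(d["dd_e"]))


__all__ = [
    "AgeDistribution",
    "BriereParams",
    "ChamberDataset",
    "DiapauseGrid",
    "DiapauseParams",
    "EmergenceTrajectory",
    "FieldSurvey",
    "GammaFit",
    "MEDITERRANEAN",
    "PopulationState",
    "StageParamSet",
    "TemperatureSeries",
    "WeatherSpec",
    "briere_optimum",
    "briere_rate",
    "calibrate_diapause",
    "calibrate_rates",
    "cumulative_emergence_at",
    "default_age_distribution",
    "default_diapause",
    "degree_days",
    "diapause_termination_day",
    "entry_cdf_constant",
    "entry_times_constant",
    "entry_times_series",
    "evaluate_fit",
    "fit_development_params",
    "fit_gamma_emergence",
    "generate_chamber_experiment",
    "generate_field_survey",
    "generate_temperature_series",
    "initialize",
    "load_param_file",
    "load_preset",
    "scale_from_max",
    "simulate",
    "step",
]
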