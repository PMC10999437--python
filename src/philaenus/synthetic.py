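"""Synthetic temperature, chamber-experiment and field-survey generators.

No public accessions of the original rearing or survey datasets exist, so
testing and worked examples rest on generators that emulate the study
designs the model assumes:

* a sinusoidal-plus-noise weather generator (annual cycle, diurnal cycle,
  Gaussian noise) standing in for data-logger / reanalysis series;
* constant-temperature chamber cohorts (default 10/18/24/30 °C, nine
  replicates, censused Monday/Wednesday/Friday), with individual
  emergence times sampled exactly along characteristics from
  Beta-distributed initial egg ages — deliberately independent of the
  finite-volume solver so solver tests are non-circular;
* weekly field surveys of the nymphal instars from early March to late
  May, generated by the full forward model (diapause + stage transport)
  with binomial observation noise on a finite cohort.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibrate import FieldSurvey
from .characteristics import entry_cdf_constant, entry_times_constant
from .diapause import DiapauseParams
from .kolmogorov import AgeDistribution, STAGE_LABELS, cumulative_emergence_at, simulate
from .parameterize import ChamberDataset
from .rates import StageParamSet
from .temperature import TemperatureSeries

__all__ = [
    "WeatherSpec",
    "MEDITERRANEAN",
    "generate_temperature_series",
    "generate_chamber_experiment",
    "generate_field_survey",
]


@dataclass(frozen=True)
class WeatherSpec:
    """Parameters of the sinusoidal weather generator.

    T(t) = mean − annual_amplitude·cos(2π·day/365)
              + diurnal_amplitude·sin(2π·hour/24) + ε,  ε ~ N(0, noise_sd²).
    """

    mean: float = 15.0
    annual_amplitude: float = 8.0
    diurnal_amplitude: float = 4.0
    noise_sd: float = 1.5
    cadence: str = "hourly"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.annual_amplitude < 0 or self.diurnal_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cadence not in ("hourly", "daily"):
            raise ValueError(f"cadence must be 'hourly' or 'daily', got {self.cadence!r}")


#: Default mid-latitude coastal climate: mild winters, warm summers.
MEDITERRANEAN = WeatherSpec()


def generate_temperature_series(
    spec: WeatherSpec, days: int = 365, start_day: int = 1
) -> TemperatureSeries:
    """Generate a temperature series of ``days`` days from Jan 1 (day 1)."""
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(spec.seed)
    if spec.cadence == "daily":
        d = start_day - 1 + np.arange(days)
        vals = (
            spec.mean
            - spec.annual_amplitude * np.cos(2 * np.pi * d / 365.0)
            + rng.normal(0.0, spec.noise_sd, size=days)
        )
        return TemperatureSeries.from_daily(vals, start_day=start_day)
    hours = np.arange(days * 24)
    day_frac = start_day - 1 + hours / 24.0
    vals = (
        spec.mean
        - spec.annual_amplitude * np.cos(2 * np.pi * day_frac / 365.0)
        + spec.diurnal_amplitude * np.sin(2 * np.pi * (hours % 24) / 24.0)
        + rng.normal(0.0, spec.noise_sd, size=len(hours))
    )
    return TemperatureSeries.from_hourly(vals, start_day=start_day)


# ---------------------------------------------------------------------------
# Chamber experiments
# ---------------------------------------------------------------------------

def _census_days(horizon: int) -> np.ndarray:
    """Monday/Wednesday/Friday census schedule: days 1, 3, 5, 8, 10, 12, ..."""
    days = np.arange(1, horizon + 1)
    return days[np.isin(days % 7, (1, 3, 5))]


def _auto_horizon(
    params: StageParamSet, age_dist: AgeDistribution, temp: float, cap: int = 400
) -> int:
    """Census long enough for ~99.9% of the cohort to reach adulthood."""
    v = params.rates(temp)
    if v[0] <= 0 or np.any(v[1:] <= 0):
        return 100  # nothing (or not everything) develops; a fixed window
    slowest_x0 = float(age_dist.ppf(0.001))
    t_end = (1.0 - slowest_x0) / v[0] + float(np.sum(1.0 / v[1:]))
    return int(min(cap, math.ceil(t_end) + 7))


def generate_chamber_experiment(
    params: StageParamSet,
    age_dist: AgeDistribution,
    temps: Sequence[float] = (10.0, 18.0, 24.0, 30.0),
    n_replicates: int = 9,
    cohort_size: int = 20,
    seed: int = 0,
    horizon: Optional[int] = None,
    analytic: bool = False,
) -> list[ChamberDataset]:
    """Simulate the constant-temperature cohort experiments.

    Each replicate holds ``cohort_size`` eggs with Beta-distributed
    initial ages; individual stage-entry times follow the exact
    characteristics solution and are censored to the thrice-weekly
    census.  ``analytic=True`` returns the infinite-cohort limit instead:
    a single pooled pseudo-replicate whose (fractional) counts equal the
    characteristics CDF scaled to the total cohort.
    """
    rng = np.random.default_rng(seed)
    out = []
    labels = list(STAGE_LABELS.values())
    for temp in temps:
        h = horizon if horizon is not None else _auto_horizon(params, age_dist, temp)
        days = _census_days(h)
        rows = []
        if analytic:
            total = float(n_replicates * cohort_size)
            for stage_idx, label in zip(range(2, 8), labels):
                cdf = entry_cdf_constant(days.astype(float), stage_idx, age_dist, params, temp)
                for d, c in zip(days, cdf * total):
                    rows.append(("pooled", int(d), label, c))
            n_cohort = total
        else:
            n_cohort = float(n_replicates * cohort_size)
            for rep in range(1, n_replicates + 1):
                x0 = age_dist.dist.rvs(size=cohort_size, random_state=rng)
                entry = entry_times_constant(x0, params, temp)  # (n, 6)
                for col, label in enumerate(labels):
                    counts = (entry[:, col][None, :] <= days[:, None]).sum(axis=1)
                    for d, c in zip(days, counts):
                        rows.append((f"rep{rep}", int(d), label, float(c)))
        df = pd.DataFrame(rows, columns=["replicate", "day", "stage", "cumulative_count"])
        out.append(ChamberDataset(temperature=float(temp), observations=df, n_cohort=n_cohort))
    return out


# ---------------------------------------------------------------------------
# Field surveys
# ---------------------------------------------------------------------------

#: inter-site climatic offsets (°C) cycled over sites: typical 1-2 °C
#: variation among nearby lowland/hill locations
SITE_MEAN_OFFSETS = (0.0, 1.5, -1.0, 0.5)


def generate_field_survey(
    stage_params: StageParamSet,
    age_dist: AgeDistribution,
    diapause: DiapauseParams,
    weather: WeatherSpec = MEDITERRANEAN,
    n_sites: int = 4,
    year: int = 2017,
    cohort: int = 100,
    seed: int = 0,
    sampling_start: int = 64,
    sampling_end: int = 148,
    sampling_step: int = 7,
    noiseless: bool = False,
    grid_cells: int = 200,
) -> list[FieldSurvey]:
    """Generate weekly field surveys (early March - late May) per site.

    Each site gets its own weather realization (mean shifted by the
    cycled :data:`SITE_MEAN_OFFSETS`, independent noise), the full
    forward model is run, and the cumulative emergence of N1-N5 is read
    on the weekly dates.  With ``noiseless=False`` each date receives
    independent binomial observation noise on a ``cohort``-sized sample,
    monotonized by a running maximum so cumulative curves remain valid.
    The first-adult date is the simulated 1%-adult day.
    """
    surveys = []
    horizon = sampling_end + 10
    dates = np.arange(sampling_start, sampling_end + 1, sampling_step)
    for j in range(n_sites):
        offset = SITE_MEAN_OFFSETS[j % len(SITE_MEAN_OFFSETS)]
        site_seed = int((weather.seed + seed + 1_000_003 * (j + 1)) % 2**31)
        spec = replace(weather, mean=weather.mean + offset, seed=site_seed)
        temps = generate_temperature_series(spec, days=horizon)
        traj = simulate(
            temps,
            stage_params,
            diapause,
            age_dist=age_dist,
            horizon=horizon,
            n_eggs=100.0,
            grid_cells=grid_cells,
        )
        rng = np.random.default_rng((site_seed + 17) % 2**31)
        rows = []
        for stage, idx in (("N1", 2), ("N2", 3), ("N3", 4), ("N4", 5), ("N5", 6)):
            pct = cumulative_emergence_at(traj, idx, dates)
            if noiseless:
                obs = pct
            else:
                obs = rng.binomial(cohort, np.clip(pct / 100.0, 0.0, 1.0)) / cohort * 100.0
                obs = np.maximum.accumulate(obs)
            for d, p in zip(dates, obs):
                rows.append((int(d), stage, float(p)))
        df = pd.DataFrame(rows, columns=["date", "stage", "cumulative_percent"])
        surveys.append(
            FieldSurvey(
                site=f"site{j + 1}",
                year=year,
                data=df,
                temps=temps,
                first_adult_day=traj.emergence_date(7, 1.0),
            )
        )
    return surveys
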