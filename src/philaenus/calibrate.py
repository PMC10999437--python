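"""Two-step field calibration of the phenology model.

Step (i) refines the stage rate-function parameters against weekly field
emergence curves of the nymphal instars (plus a half-weight penalty on
the first-adult appearance date).  Step (ii) fixes the rates and grid
searches the diapause-termination pair (t_e, dd_e), with the objective
restricted to the 3rd-5th instar curves — the stages the field data
resolve best and the targets of monitoring and control.

The candidate grids span t_e ∈ [3.0, 10.0] °C and dd_e ∈ [30, 130] DD.
Grid steps default to 0.5 °C and 10 DD.  The search is exhaustive and
deterministic; ties are broken by smaller dd_e, then smaller t_e.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .diapause import DiapauseParams, diapause_termination_day
from .kolmogorov import (
    AgeDistribution,
    EmergenceTrajectory,
    cumulative_emergence_at,
    simulate,
)
from .parameterize import BOUNDS
from .rates import BriereParams, StageParamSet
from .temperature import TemperatureSeries

__all__ = [
    "FieldSurvey",
    "DiapauseGrid",
    "calibrate_rates",
    "calibrate_diapause",
    "survey_objective",
]

NYMPH_STAGES = ("N1", "N2", "N3", "N4", "N5")
LATE_INSTARS = ("N3", "N4", "N5")
_STAGE_INDEX = {"N1": 2, "N2": 3, "N3": 4, "N4": 5, "N5": 6, "adult": 7}


@dataclass
class FieldSurvey:
    """One site-year of weekly nymphal-stage field sampling.

    ``data`` is long-format with columns (date, stage, cumulative_percent):
    per weekly sampling date (Julian day), the cumulative emergence (%) of
    each nymphal instar N1-N5.  ``first_adult_day`` is the Julian day of
    the first adult observation (if recorded).  The paired temperature
    series drives the model for this site-year.
    """

    site: str
    year: int
    data: pd.DataFrame
    temps: TemperatureSeries
    first_adult_day: Optional[float] = None

    def __post_init__(self) -> None:
        required = {"date", "stage", "cumulative_percent"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"survey data missing columns {sorted(missing)}")
        bad = (
            self.data.sort_values("date")
            .groupby("stage")["cumulative_percent"]
            .apply(lambda s: bool((s.diff().dropna() < -1e-9).any()))
        )
        if bad.any():
            raise ValueError(
                f"cumulative percentages must be non-decreasing; offending stages: "
                f"{list(bad[bad].index)}"
            )

    @property
    def dates(self) -> np.ndarray:
        return np.sort(self.data["date"].unique()).astype(float)

    def percent_curve(self, stage: str) -> pd.Series:
        sub = self.data[self.data.stage == stage].sort_values("date")
        return pd.Series(sub["cumulative_percent"].to_numpy(), index=sub["date"].to_numpy())

    @property
    def horizon(self) -> int:
        h = int(np.ceil(self.dates[-1]))
        if self.first_adult_day is not None:
            h = max(h, int(np.ceil(self.first_adult_day)))
        return h


@dataclass(frozen=True)
class DiapauseGrid:
    """Candidate grids for the diapause-termination search."""

    t_e_values: tuple = field(
        default_factory=lambda: tuple(np.round(np.arange(3.0, 10.0 + 1e-9, 0.5), 3))
    )
    dd_e_values: tuple = field(
        default_factory=lambda: tuple(np.round(np.arange(30.0, 130.0 + 1e-9, 10.0), 3))
    )

    def __post_init__(self) -> None:
        te = np.asarray(self.t_e_values)
        dd = np.asarray(self.dd_e_values)
        if te.min() < 3.0 - 1e-9 or te.max() > 10.0 + 1e-9:
            raise ValueError("t_e grid must lie within [3.0, 10.0] °C")
        if dd.min() < 30.0 - 1e-9 or dd.max() > 130.0 + 1e-9:
            raise ValueError("dd_e grid must lie within [30, 130] DD")


def survey_objective(
    survey: FieldSurvey,
    traj: EmergenceTrajectory,
    stages: Sequence[str] = NYMPH_STAGES,
    adult_penalty_weight: float = 0.0,
) -> float:
    """Summed squared differences (%) between survey and simulated curves.

    Optionally adds ``weight * (sim_1%_adult_day − observed_first_adult_day)²``
    when the survey records a first-adult date.
    """
    total = 0.0
    dates = survey.dates
    dates = dates[dates <= traj.days[-1] + 1e-9]
    for stage in stages:
        obs = survey.percent_curve(stage)
        obs = obs[obs.index <= traj.days[-1] + 1e-9]
        if obs.empty:
            continue
        sim = cumulative_emergence_at(traj, _STAGE_INDEX[stage], obs.index.to_numpy())
        total += float(np.sum((obs.to_numpy() - sim) ** 2))
    if adult_penalty_weight > 0 and survey.first_adult_day is not None:
        sim_day = traj.emergence_date(7, 1.0)
        if sim_day is None:
            sim_day = float(traj.days[-1])  # never emerged: worst case at horizon
        total += adult_penalty_weight * (sim_day - survey.first_adult_day) ** 2
    return total


def _simulate_survey(
    survey: FieldSurvey,
    params: StageParamSet,
    age_dist: AgeDistribution,
    term_day: Optional[int],
    grid_cells: int,
) -> EmergenceTrajectory:
    return simulate(
        survey.temps,
        params,
        diapause=None,
        age_dist=age_dist,
        horizon=survey.horizon,
        grid_cells=grid_cells,
        start_day=term_day if term_day is not None else survey.horizon + 1,
    )


def calibrate_rates(
    surveys: Sequence[FieldSurvey],
    start: StageParamSet,
    age_dist: AgeDistribution,
    diapause: DiapauseParams,
    grid_cells: int = 100,
    maxfev_per_stage: int = 80,
    adult_penalty_weight: float = 0.5,
) -> tuple[StageParamSet, dict]:
    """Refine stage rate parameters against field survey curves.

    A provisional diapause pair fixes the development start of each
    site-year; the per-stage Brière triples are then refined sequentially
    (egg first, instars in order) by bounded Nelder-Mead on the summed
    squared differences across all surveys and nymphal stages, with a
    half-weight squared-day penalty on the 1%-adult date.  The returned
    objective never exceeds that of ``start``.
    """
    for s in surveys:
        if len(s.dates) < 5:
            raise ValueError(f"survey {s.site}/{s.year} has fewer than 5 sampling dates")
    term_days = [diapause_termination_day(s.temps, diapause) for s in surveys]

    def total_objective(params: StageParamSet) -> float:
        tot = 0.0
        for s, term in zip(surveys, term_days):
            traj = _simulate_survey(s, params, age_dist, term, grid_cells)
            tot += survey_objective(
                s, traj, NYMPH_STAGES, adult_penalty_weight=adult_penalty_weight
            )
        return tot

    fitted = list(start.stages)
    initial = total_objective(start)
    trace = [initial]

    for i in range(6):
        def stage_obj(x, i=i):
            v_max, t_inf, t_sup = x
            if t_sup - t_inf < 5.0:
                return 1e12
            try:
                p = BriereParams.from_max_rate(v_max, t_inf, t_sup)
            except ValueError:
                return 1e12
            trial = list(fitted)
            trial[i] = p
            return total_objective(StageParamSet(tuple(trial)))

        p0 = fitted[i]
        x0 = [p0.max_rate, p0.t_inf, p0.t_sup]
        res = optimize.minimize(
            stage_obj,
            x0,
            method="Nelder-Mead",
            bounds=[BOUNDS["v_max"], BOUNDS["t_inf"], BOUNDS["t_sup"]],
            options={"xatol": 1e-6, "fatol": 1e-1, "maxfev": maxfev_per_stage, "adaptive": True},
        )
        if res.fun <= stage_obj(np.asarray(x0)):
            fitted[i] = BriereParams.from_max_rate(*res.x)
        trace.append(float(res.fun))

    final_params = StageParamSet(tuple(fitted))
    final = total_objective(final_params)
    if final > initial:  # pragma: no cover - safeguard
        return start, {"initial_objective": initial, "final_objective": initial, "trace": trace}
    return final_params, {
        "initial_objective": initial,
        "final_objective": final,
        "trace": trace,
    }


def calibrate_diapause(
    surveys: Sequence[FieldSurvey],
    rates: StageParamSet,
    age_dist: AgeDistribution,
    grid: DiapauseGrid = DiapauseGrid(),
    grid_cells: int = 200,
) -> tuple[DiapauseParams, pd.DataFrame]:
    """Exhaustive grid search for the diapause-termination pair.

    Every (t_e, dd_e) candidate is scored by the summed squared
    differences between observed and simulated cumulative emergence of
    the 3rd-5th instars across all surveys.  Pairs for which diapause
    never terminates in a survey contribute that survey's all-zero
    prediction (a natural penalty, not an exception).  Returns the
    arg-min pair (ties: smaller dd_e, then smaller t_e) and the full
    objective surface as a (t_e, dd_e, objective) table.
    """
    # termination day depends on the pair only through the survey's
    # degree-day series, and the forward run only on the termination day:
    # cache trajectories per (survey, termination day).
    traj_cache: list[dict] = [dict() for _ in surveys]

    def traj_for(si: int, term: Optional[int]) -> EmergenceTrajectory:
        key = term if term is not None else -1
        if key not in traj_cache[si]:
            traj_cache[si][key] = _simulate_survey(
                surveys[si], rates, age_dist, term, grid_cells
            )
        return traj_cache[si][key]

    rows = []
    for t_e in grid.t_e_values:
        for dd_e in grid.dd_e_values:
            pair = DiapauseParams(t_e=float(t_e), dd_e=float(dd_e))
            obj = 0.0
            for si, s in enumerate(surveys):
                term = diapause_termination_day(s.temps, pair)
                traj = traj_for(si, term)
                obj += survey_objective(s, traj, LATE_INSTARS)
            rows.append((float(t_e), float(dd_e), obj))
    surface = pd.DataFrame(rows, columns=["t_e", "dd_e", "objective"])
    best = surface.sort_values(["objective", "dd_e", "t_e"], kind="mergesort").iloc[0]
    return DiapauseParams(t_e=float(best.t_e), dd_e=float(best.dd_e)), surface
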