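"""Estimation of development rates from constant-temperature chamber cohorts.

Cohorts of field-collected eggs are reared at constant temperatures
(10, 18, 24 and 30 °C; nine replicates each) and censused three times a
week; the observable is, per census day, the cumulative number of
individuals that have reached each stage.  Two estimation layers are
provided:

* :func:`fit_gamma_emergence` — approximates a stage's pooled cumulative
  emergence curve at one temperature with a Gamma CDF (a smoothing /
  visualization layer, and a source of pseudo-observations at arbitrary
  dates).
* :func:`fit_development_params` — estimates the per-stage Brière
  parameters and the initial Beta age distribution of eggs by least
  squares between observed and simulated cumulative emergence
  percentages across all four temperatures.  Because chamber temperature
  is constant, the transport model is integrated exactly along
  characteristics, and the diapause phase is bypassed (chamber eggs are
  post-storage).

The minimization is a bounded derivative-free local search from a
user-supplied initial guess, stopping on a parameter-step tolerance of
1e-6 or an objective-change tolerance of 1e-1 (objective in squared
percentage points).  Stages are fitted sequentially in developmental
order: the egg stage (jointly with the Beta age distribution) from the
hatch curves, then each instar from its entry curves with upstream
parameters held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .characteristics import entry_cdf_constant
from .kolmogorov import AgeDistribution, STAGE_LABELS
from .rates import BriereParams, StageParamSet

__all__ = [
    "ChamberDataset",
    "GammaFit",
    "fit_gamma_emergence",
    "fit_development_params",
    "chamber_objective",
]

#: emergence-curve labels in developmental order (entries into stages 2..7)
EMERGENCE_STAGES = tuple(STAGE_LABELS.values())

#: parameter bounds used by all fitting routines
BOUNDS = {
    "v_max": (1e-4, 1.0),
    "t_inf": (0.0, 15.0),
    "t_sup": (25.0, 40.0),
    "shape": (0.05, 50.0),
}


@dataclass
class ChamberDataset:
    """One constant-temperature chamber treatment.

    ``observations`` is a long-format table with columns
    (replicate, day, stage, cumulative_count): per census day, the
    cumulative number of individuals of each replicate that have reached
    the stage ("N1" counts hatched eggs, ... , "adult" emerged adults).
    """

    temperature: float
    observations: pd.DataFrame
    n_cohort: Optional[float] = None  # total individuals across replicates

    def __post_init__(self) -> None:
        required = {"replicate", "day", "stage", "cumulative_count"}
        missing = required - set(self.observations.columns)
        if missing:
            raise ValueError(f"chamber observations missing columns {sorted(missing)}")
        bad = (
            self.observations.sort_values("day")
            .groupby(["replicate", "stage"])["cumulative_count"]
            .apply(lambda s: bool((s.diff().dropna() < 0).any()))
        )
        if bad.any():
            raise ValueError(
                "cumulative counts must be non-decreasing in time; offending "
                f"(replicate, stage): {list(bad[bad].index[:3])}"
            )
        if self.n_cohort is None:
            # fall back: every individual eventually hatches in this model
            per_rep = self.observations[self.observations.stage == "N1"].groupby(
                "replicate"
            )["cumulative_count"].max()
            self.n_cohort = float(per_rep.sum())

    @property
    def observation_days(self) -> np.ndarray:
        return np.sort(self.observations["day"].unique()).astype(float)

    def pooled_percent(self, stage: str) -> pd.Series:
        """Pooled cumulative emergence (%) of a stage across replicates."""
        sub = self.observations[self.observations.stage == stage]
        pooled = sub.groupby("day")["cumulative_count"].sum().sort_index()
        return pooled / self.n_cohort * 100.0


@dataclass(frozen=True)
class GammaFit:
    """Gamma approximation of one stage/temperature emergence curve."""

    shape: float
    scale: float
    stage: str
    temperature: float
    degenerate: bool = False

    def cdf(self, days) -> np.ndarray:
        return stats.gamma.cdf(np.asarray(days, dtype=float), self.shape, scale=self.scale)

    @property
    def mean_day(self) -> float:
        return self.shape * self.scale


def fit_gamma_emergence(dataset: ChamberDataset, stage: str) -> GammaFit:
    """Least-squares Gamma-CDF fit to a stage's pooled emergence curve.

    The pooled cumulative fraction (normalized to its own final level, so
    the fit is invariant to cohort size) is matched by a Gamma CDF in
    (shape, scale), optimized in log-space from a method-of-moments
    start.  Near-degenerate data (all emergence at a single census)
    yields a point-mass-like fit with a warning.
    """
    pooled = dataset.pooled_percent(stage)
    final = pooled.iloc[-1]
    if final <= 0:
        raise ValueError(f"no emergence observed for stage {stage}")
    days = pooled.index.to_numpy(dtype=float)
    frac = (pooled / final).to_numpy()
    increments = np.diff(np.concatenate([[0.0], frac]))
    if np.count_nonzero(increments > 0) < 1:
        raise ValueError("degenerate data: no positive emergence increments")
    mean = float(np.sum(days * increments) / np.sum(increments))
    var = float(np.sum((days - mean) ** 2 * increments) / np.sum(increments))
    degenerate = var <= 1e-12
    if degenerate:
        warnings.warn(
            f"all emergence of stage {stage} at T={dataset.temperature} °C occurs "
            "at a single census; Gamma fit degenerates toward a point mass at "
            f"day {mean:g}",
            stacklevel=2,
        )
        var = max(var, 1e-4)
    shape0 = max(mean**2 / var, 1e-3)
    scale0 = max(var / mean, 1e-6)

    def resid(logp):
        k, s = np.exp(logp)
        return stats.gamma.cdf(days, k, scale=s) - frac

    sol = optimize.least_squares(resid, np.log([shape0, scale0]), method="lm")
    k, s = np.exp(sol.x)
    return GammaFit(
        shape=float(k),
        scale=float(s),
        stage=stage,
        temperature=dataset.temperature,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Development-parameter estimation
# ---------------------------------------------------------------------------


def _predicted_percent(
    days: np.ndarray,
    stage_index: int,
    age_dist: AgeDistribution,
    params: StageParamSet,
    temp: float,
) -> np.ndarray:
    """Model cumulative emergence (%) into stage 2..7 at constant temp."""
    return 100.0 * entry_cdf_constant(days, stage_index, age_dist, params, temp)


def _observed_curves(
    datasets: Sequence[ChamberDataset], target: str
) -> dict[tuple[float, str], pd.Series]:
    """(temperature, stage) -> observed pooled percent curve."""
    curves: dict[tuple[float, str], pd.Series] = {}
    for ds in datasets:
        for stage in EMERGENCE_STAGES:
            if not (ds.observations.stage == stage).any():
                continue
            pooled = ds.pooled_percent(stage)
            if target == "gamma" and pooled.iloc[-1] > 0:
                gf = fit_gamma_emergence(ds, stage)
                smooth = gf.cdf(pooled.index.to_numpy()) * pooled.iloc[-1]
                pooled = pd.Series(smooth, index=pooled.index)
            curves[(ds.temperature, stage)] = pooled
    return curves


def chamber_objective(
    datasets: Sequence[ChamberDataset],
    params: StageParamSet,
    age_dist: AgeDistribution,
    target: str = "raw",
) -> float:
    """Summed squared differences (%) between observed and model curves."""
    curves = _observed_curves(datasets, target)
    total = 0.0
    for (temp, stage), obs in curves.items():
        idx = EMERGENCE_STAGES.index(stage) + 2
        pred = _predicted_percent(obs.index.to_numpy(dtype=float), idx, age_dist, params, temp)
        total += float(np.sum((obs.to_numpy() - pred) ** 2))
    return total


@dataclass
class FitReport:
    """Objective trace and diagnostics from fit_development_params."""

    initial_objective: float
    final_objective: float
    stage_objectives: dict = field(default_factory=dict)
    converged: bool = True
    messages: list = field(default_factory=list)


def _minimize(fun, x0, bounds, maxfev):
    """Bounded Nelder-Mead with the stated stopping tolerances."""
    res = optimize.minimize(
        fun,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={
            "xatol": 1e-6,
            "fatol": 1e-1,
            "maxfev": maxfev,
            "adaptive": True,
        },
    )
    return res


def fit_development_params(
    datasets: Sequence[ChamberDataset],
    init_params: StageParamSet,
    init_age: AgeDistribution,
    target: str = "raw",
    maxfev: int = 4000,
) -> tuple[StageParamSet, AgeDistribution, FitReport]:
    """Estimate Brière parameters and the egg age distribution from chamber data.

    Sequential bounded least squares in developmental order: first
    (v_max, t_inf, t_sup) of the egg stage jointly with (alpha, beta) of
    the Beta age distribution against the hatch curves at the four
    temperatures, then each instar's triple against its entry curves.
    ``target="gamma"`` fits the Gamma-smoothed curves instead of the raw
    censored observations.  The returned objective never exceeds the
    initial one (best-so-far is kept on non-convergence).
    """
    if len({ds.temperature for ds in datasets}) < 2:
        warnings.warn("fewer than two temperature treatments; thresholds weakly identified", stacklevel=2)
    curves = _observed_curves(datasets, target)
    report = FitReport(
        initial_objective=chamber_objective(datasets, init_params, init_age, target),
        final_objective=np.nan,
    )

    fitted = list(init_params.stages)
    age = init_age

    def stage_obs(stage_label):
        return [
            (temp, obs)
            for (temp, st), obs in curves.items()
            if st == stage_label
        ]

    # --- egg stage + age distribution (hatch curves = entries into N1) ---
    obs1 = stage_obs("N1")
    if not obs1:
        raise ValueError("chamber data contain no hatch (N1) observations")

    def egg_objective(x):
        v_max, t_inf, t_sup, alpha, beta = x
        if t_sup - t_inf < 5.0:
            return 1e12
        try:
            p = BriereParams.from_max_rate(v_max, t_inf, t_sup)
            a_dist = AgeDistribution(alpha, beta)
        except ValueError:
            return 1e12
        trial = StageParamSet(tuple([p] + fitted[1:]))
        tot = 0.0
        for temp, obs in obs1:
            pred = _predicted_percent(obs.index.to_numpy(dtype=float), 2, a_dist, trial, temp)
            tot += float(np.sum((obs.to_numpy() - pred) ** 2))
        return tot

    egg0 = init_params[0]
    x0 = [egg0.max_rate, egg0.t_inf, egg0.t_sup, init_age.alpha, init_age.beta]
    res = _minimize(
        egg_objective,
        x0,
        bounds=[BOUNDS["v_max"], BOUNDS["t_inf"], BOUNDS["t_sup"], BOUNDS["shape"], BOUNDS["shape"]],
        maxfev=maxfev,
    )
    if egg_objective(res.x) <= egg_objective(np.asarray(x0)):
        v_max, t_inf, t_sup, alpha, beta = res.x
        fitted[0] = BriereParams.from_max_rate(v_max, t_inf, t_sup)
        age = AgeDistribution(alpha, beta)
    else:  # pragma: no cover - optimizer regressions only
        report.messages.append("egg-stage fit did not improve; keeping initial guess")
        report.converged = False
    report.stage_objectives["egg"] = float(res.fun)
    if not res.success:
        report.converged = False
        report.messages.append(f"egg stage: {res.message}")

    # --- instars N1..N5 (entry curves into stages 3..7) ------------------
    for i, label in enumerate(("N2", "N3", "N4", "N5", "adult"), start=1):
        obs_k = stage_obs(label)
        if not obs_k:
            report.messages.append(f"no observations for {label}; stage {i} kept at initial guess")
            continue

        def instar_objective(x, i=i, obs_k=obs_k):
            v_max, t_inf, t_sup = x
            if t_sup - t_inf < 5.0:
                return 1e12
            try:
                p = BriereParams.from_max_rate(v_max, t_inf, t_sup)
            except ValueError:
                return 1e12
            trial_list = list(fitted)
            trial_list[i] = p
            trial = StageParamSet(tuple(trial_list))
            tot = 0.0
            for temp, obs in obs_k:
                pred = _predicted_percent(
                    obs.index.to_numpy(dtype=float), i + 2, age, trial, temp
                )
                tot += float(np.sum((obs.to_numpy() - pred) ** 2))
            return tot

        p0 = init_params[i]
        x0 = [p0.max_rate, p0.t_inf, p0.t_sup]
        res = _minimize(
            instar_objective,
            x0,
            bounds=[BOUNDS["v_max"], BOUNDS["t_inf"], BOUNDS["t_sup"]],
            maxfev=maxfev,
        )
        if instar_objective(res.x) <= instar_objective(np.asarray(x0)):
            fitted[i] = BriereParams.from_max_rate(*res.x)
        report.stage_objectives[EMERGENCE_STAGES[i - 1]] = float(res.fun)
        if not res.success:
            report.converged = False
            report.messages.append(f"stage {i}: {res.message}")

    final_params = StageParamSet(tuple(fitted))
    report.final_objective = chamber_objective(datasets, final_params, age, target)
    if report.final_objective > report.initial_objective:  # pragma: no cover
        report.messages.append("sequential fit worsened total objective; reverting")
        report.converged = False
        return init_params, init_age, report
    return final_params, age, report
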