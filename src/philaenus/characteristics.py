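"""Exact method-of-characteristics solutions of the age-transport model.

Pure advection along physiological age means every individual keeps its
rank: an egg starting at age x0 hatches when its accumulated development
∫ v_egg(T(t)) dt reaches 1 − x0, then traverses each instar when the
instar's integral reaches 1.  At constant temperature this reduces to
closed-form entry times

    t_hatch(x0) = (1 − x0) / v_1(T),
    t_enter_stage_k(x0) = t_hatch(x0) + Σ_{i=2}^{k−1} 1 / v_i(T).

These solutions are independent of the finite-volume solver and serve
both as the sampling engine of the chamber-experiment generator and as
an oracle in solver tests, as well as the fast exact forward model when
fitting chamber data (where temperature is constant by design).
"""

from __future__ import annotations

import numpy as np

from .kolmogorov import AgeDistribution
from .rates import StageParamSet
from .temperature import TemperatureSeries

__all__ = [
    "entry_times_constant",
    "entry_cdf_constant",
    "entry_times_series",
]


def entry_times_constant(
    x0: np.ndarray, params: StageParamSet, temp: float
) -> np.ndarray:
    """Entry times into stages 2..7 for individuals with initial egg ages x0.

    Returns an array of shape (len(x0), 6); column k is the time (days
    from the start of development) at which each individual enters stage
    k + 2.  Stages whose rate is zero at ``temp`` yield +inf from that
    column onward.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    v = params.rates(temp)
    with np.errstate(divide="ignore"):
        hatch = np.where(v[0] > 0, (1.0 - x0) / v[0], np.inf)
        durations = np.where(v[1:] > 0, 1.0 / v[1:], np.inf)  # N1..N5
    offsets = np.concatenate([[0.0], np.cumsum(durations)])  # stages 2..7
    return hatch[:, None] + offsets[None, :]


def entry_cdf_constant(
    dates: np.ndarray,
    stage: int,
    age_dist: AgeDistribution,
    params: StageParamSet,
    temp: float,
) -> np.ndarray:
    """Fraction of the cohort having entered ``stage`` (2..7) by each date.

    Exact infinite-cohort limit: the entry-time distribution is the
    push-forward of the initial Beta age distribution through the
    characteristics map, so
    P(entry_k <= d) = P(x0 >= 1 − v_1 (d − offset_k)).
    """
    if not 2 <= stage <= 7:
        raise ValueError(f"stage must be in 2..7, got {stage}")
    dates = np.asarray(dates, dtype=float)
    v = params.rates(temp)
    if v[0] <= 0 or np.any(v[1 : stage - 1] <= 0):
        return np.zeros_like(dates)
    offset = float(np.sum(1.0 / v[1 : stage - 1]))  # durations of N1..N_{k-2}
    arg = 1.0 - v[0] * (dates - offset)
    out = np.where(dates > offset, age_dist.sf(np.clip(arg, 0.0, 1.0)), 0.0)
    return out


def entry_times_series(
    x0: np.ndarray,
    temps: TemperatureSeries,
    params: StageParamSet,
    start_day: int,
    horizon: int,
    steps_per_day: int = 96,
) -> np.ndarray:
    """Entry times (Julian days) under a time-varying temperature series.

    Development starts at the beginning of ``start_day``.  Each stage's
    cumulative development ∫ v_i dt is tabulated on a fine grid and
    inverted by interpolation.  Entries not reached by ``horizon`` are
    +inf.  Shape (len(x0), 6) for stages 2..7.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    t0 = float(start_day - 1)
    tgrid = np.linspace(t0, float(horizon), int((horizon - t0) * steps_per_day) + 1)
    if temps.cadence == "daily":
        means = temps.daily_means()
        day_idx = np.clip(np.floor(tgrid).astype(int) + 1, means.index[0], means.index[-1])
        T = means.reindex(day_idx).to_numpy()
    else:
        T = temps.at(tgrid)
    from .rates import briere_rate

    dt = tgrid[1] - tgrid[0]
    out = np.full((len(x0), 6), np.inf)
    # cumulative development of each stage along the common time grid
    dev = [np.concatenate([[0.0], np.cumsum(briere_rate(T, p)[:-1] * dt)]) for p in params]

    def invert(cum: np.ndarray, start_t: float, target: float) -> float:
        base = np.interp(start_t, tgrid, cum)
        total = cum[-1] - base
        if total < target:
            return np.inf
        return float(np.interp(base + target, cum, tgrid))

    for j, x in enumerate(x0):
        t = invert(dev[0], t0, 1.0 - x)  # hatch
        out[j, 0] = t
        for i in range(1, 6):  # instars N1..N5 -> entries into stages 3..7
            if not np.isfinite(t):
                break
            t = invert(dev[i], t, 1.0)
            out[j, i] = t
    return out
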