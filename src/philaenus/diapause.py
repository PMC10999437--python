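"""Egg diapause termination by degree-day accumulation.

Overwintering eggs resume development once they have accumulated ``dd_e``
degree-days (°C·day) above a threshold temperature ``t_e``, counted from
1 January.  Degree-days are computed from daily mean temperatures as
``max(0, T̄_d − t_e)`` summed over days; an hourly variant
(``sum of max(0, T_h − t_e) / 24``) is available for sensitivity checks.
All diapausing eggs terminate together on the first day the running sum
meets ``dd_e``; development begins on that same day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .temperature import TemperatureSeries

__all__ = ["DiapauseParams", "degree_days", "diapause_termination_day"]


@dataclass(frozen=True)
class DiapauseParams:
    """Diapause-termination thresholds.

    Parameters
    ----------
    t_e : float
        Minimum temperature threshold (°C) above which heat accumulates.
    dd_e : float
        Required cumulative degree-days (°C·day).
    """

    t_e: float
    dd_e: float

    def __post_init__(self) -> None:
        if self.dd_e < 0:
            raise ValueError(f"dd_e must be >= 0, got {self.dd_e}")


def degree_days(
    temps: TemperatureSeries,
    t_e: float,
    from_day: int = 1,
    method: str = "daily",
) -> pd.Series:
    """Running degree-day sum per Julian day, starting at ``from_day``.

    Parameters
    ----------
    temps : TemperatureSeries
        Temperature series covering ``from_day`` onward (gaps raise at
        ingestion time).
    t_e : float
        Threshold temperature (°C).
    from_day : int
        First Julian day of accumulation (1 = Jan 1).
    method : {"daily", "hourly"}
        "daily" accumulates max(0, daily mean − t_e); "hourly" accumulates
        max(0, T_h − t_e)/24 over hourly samples (falls back to "daily"
        for daily-cadence input).

    Returns
    -------
    pandas.Series
        Cumulative DD indexed by Julian day; non-decreasing.
    """
    if temps.first_day > from_day:
        raise ValueError(
            f"temperature series starts on day {temps.first_day}, "
            f"after requested accumulation start day {from_day}"
        )
    if method == "hourly" and temps.cadence == "hourly":
        day = np.floor(temps.times).astype(int) + 1
        excess = np.maximum(0.0, temps.values - t_e) / 24.0
        daily = pd.Series(excess).groupby(day).sum()
    else:
        means = temps.daily_means()
        daily = np.maximum(0.0, means - t_e)
    daily = daily[daily.index >= from_day]
    out = daily.cumsum()
    out.index.name = "julian_day"
    out.name = "cumulative_dd"
    return out


def diapause_termination_day(
    temps: TemperatureSeries,
    params: DiapauseParams,
    start: int = 1,
    method: str = "daily",
) -> Optional[int]:
    """First Julian day on which cumulative degree-days reach ``dd_e``.

    Accumulation starts on Jan 1 by default.  A zero requirement
    terminates immediately on ``start``.  Returns ``None`` if the series
    ends before the requirement is met (diapause not terminated).
    """
    if params.dd_e <= 0:
        return start
    cum = degree_days(temps, params.t_e, from_day=start, method=method)
    reached = cum[cum >= params.dd_e]
    if reached.empty:
        return None
    return int(reached.index[0])
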