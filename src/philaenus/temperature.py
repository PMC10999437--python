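"""Regularly sampled air-temperature series driving all development rates.

Time is measured in fractional days since 1 January 00:00 (so Julian day
``d`` covers the half-open interval ``[d - 1, d)``).  Series are either
hourly or daily; the cadence is auto-detected when reading CSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TemperatureSeries"]


@dataclass(frozen=True)
class TemperatureSeries:
    """Air temperatures T(t) at a regular hourly or daily cadence.

    Parameters
    ----------
    times : ndarray
        Sample times in days since Jan 1 00:00, strictly increasing with a
        constant step (1/24 for hourly, 1 for daily series).
    values : ndarray
        Air temperature (°C) at each sample time.
    """

    times: np.ndarray
    values: np.ndarray
    _daily_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if len(times) < 2:
            raise ValueError("a temperature series needs at least two samples")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("sample times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            bad = int(np.argmax(np.abs(steps - steps[0]) > 1e-9))
            raise ValueError(
                "irregular cadence / gap in temperature series between "
                f"t = {times[bad]:.4f} and t = {times[bad + 1]:.4f} days"
            )
        if np.any(~np.isfinite(values)):
            raise ValueError("temperature series contains non-finite values")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_daily(cls, daily_means, start_day: int = 1) -> "TemperatureSeries":
        """Series of daily mean temperatures; day ``start_day`` = first value."""
        vals = np.asarray(daily_means, dtype=float)
        # a daily value is nominally the mean over [d-1, d); stamp it mid-day
        times = (start_day - 1) + 0.5 + np.arange(len(vals), dtype=float)
        return cls(times, vals)

    @classmethod
    def from_hourly(cls, hourly_values, start_day: int = 1) -> "TemperatureSeries":
        vals = np.asarray(hourly_values, dtype=float)
        times = (start_day - 1) + np.arange(len(vals), dtype=float) / 24.0
        return cls(times, vals)

    @classmethod
    def from_csv(cls, path) -> "TemperatureSeries":
        """Read a (timestamp, temperature_C) CSV; cadence auto-detected."""
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        if "timestamp" not in cols:
            raise ValueError("temperature CSV is missing the 'timestamp' column")
        tcol = None
        for key in ("temperature_c", "temperature", "temp_c", "temp"):
            if key in cols:
                tcol = cols[key]
                break
        if tcol is None:
            raise ValueError("temperature CSV is missing the 'temperature_C' column")
        ts = pd.to_datetime(df[cols["timestamp"]])
        year_start = pd.Timestamp(year=ts.iloc[0].year, month=1, day=1)
        times = (ts - year_start).dt.total_seconds().to_numpy() / 86400.0
        values = df[tcol].to_numpy(dtype=float)
        step = np.diff(times)
        if len(step) and np.allclose(step, 1.0, atol=1e-6):
            # daily stamps at midnight denote that calendar day's mean
            times = times + 0.5
        return cls(times, values)

    # -- properties -------------------------------------------------------

    @property
    def cadence(self) -> str:
        step = self.times[1] - self.times[0]
        if abs(step - 1.0) < 1e-6:
            return "daily"
        if abs(step - 1.0 / 24.0) < 1e-6:
            return "hourly"
        return f"step={step:g}d"

    @property
    def first_day(self) -> int:
        return int(np.floor(self.times[0])) + 1

    @property
    def last_day(self) -> int:
        return int(np.floor(self.times[-1] - 1e-9)) + 1

    # -- accessors --------------------------------------------------------

    def daily_means(self) -> pd.Series:
        """Mean temperature per Julian day, indexed by day number."""
        if "daily" not in self._daily_cache:
            day = np.floor(self.times).astype(int) + 1
            s = pd.Series(self.values).groupby(day).mean()
            s.index.name = "julian_day"
            self._daily_cache["daily"] = s
        return self._daily_cache["daily"]

    def at(self, t) -> np.ndarray:
        """Temperature linearly interpolated at fractional day(s) ``t``."""
        return np.interp(t, self.times, self.values)

    def to_csv(self, path, year: int = 2017) -> None:
        start = pd.Timestamp(year=year, month=1, day=1)
        stamps = start + pd.to_timedelta(self.times - (0.5 if self.cadence == "daily" else 0.0), unit="D")
        pd.DataFrame({"timestamp": stamps, "temperature_C": self.values}).to_csv(
            path, index=False
        )
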