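"""CSV and YAML readers/writers shared by the library and the CLI.

CSV dialects
------------
temperature : (timestamp, temperature_C) — hourly or daily, auto-detected
chamber     : (temperature_C, replicate, day, stage, cumulative_count)
survey      : (site, year, date, stage, cumulative_percent)
trajectory  : (julian_day, stage, cumulative_count, cumulative_percent)

Dates are ISO-8601 calendar dates externally and Julian day-of-year
(day 1 = Jan 1) internally.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .calibrate import FieldSurvey
from .parameterize import ChamberDataset
from .temperature import TemperatureSeries

__all__ = [
    "RunConfig",
    "read_temperature_csv",
    "read_chamber_csv",
    "write_chamber_csv",
    "read_survey_csv",
    "write_survey_csv",
]


@dataclass
class RunConfig:
    """Resolved configuration of a CLI run; archived alongside outputs."""

    command: str
    seed: int = 0
    preset: Optional[str] = None
    params_file: Optional[str] = None
    temperature_file: Optional[str] = None
    survey_file: Optional[str] = None
    chamber_file: Optional[str] = None
    out_dir: str = "."
    grid_cells: int = 200
    horizon_days: int = 365
    extra: dict = field(default_factory=dict)

    def archive(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "run_config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path


def _require_columns(df: pd.DataFrame, required: set, what: str, path) -> None:
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{what} CSV {path} is missing column(s): {', '.join(missing)}")


def read_temperature_csv(path) -> TemperatureSeries:
    return TemperatureSeries.from_csv(path)


def read_chamber_csv(path) -> list[ChamberDataset]:
    df = pd.read_csv(path)
    _require_columns(
        df, {"temperature_C", "replicate", "day", "stage", "cumulative_count"}, "chamber", path
    )
    if df.empty:
        raise ValueError(f"chamber CSV {path} contains no observations")
    out = []
    for temp, sub in df.groupby("temperature_C"):
        out.append(
            ChamberDataset(
                temperature=float(temp),
                observations=sub[["replicate", "day", "stage", "cumulative_count"]].reset_index(
                    drop=True
                ),
            )
        )
    return out


def write_chamber_csv(datasets: list[ChamberDataset], path) -> None:
    frames = []
    for ds in datasets:
        sub = ds.observations.copy()
        sub.insert(0, "temperature_C", ds.temperature)
        frames.append(sub)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_survey_csv(survey_path, temperature_paths) -> list[FieldSurvey]:
    """Read surveys paired with their temperature series.

    ``temperature_paths`` maps (site, year) or site to a temperature CSV;
    a single path (str/Path) applies to every survey.
    """
    df = pd.read_csv(survey_path)
    _require_columns(
        df, {"site", "year", "date", "stage", "cumulative_percent"}, "survey", survey_path
    )
    single = None if isinstance(temperature_paths, dict) else temperature_paths
    out = []
    for (site, year), sub in df.groupby(["site", "year"]):
        if single is not None:
            tpath = single
        else:
            key = (site, int(year)) if (site, int(year)) in temperature_paths else site
            if key not in temperature_paths:
                raise ValueError(f"no temperature file provided for survey {site}/{year}")
            tpath = temperature_paths[key]
        temps = read_temperature_csv(tpath)
        first_adult = None
        if "first_adult_day" in sub.columns and sub["first_adult_day"].notna().any():
            first_adult = float(sub["first_adult_day"].dropna().iloc[0])
        out.append(
            FieldSurvey(
                site=str(site),
                year=int(year),
                data=sub[["date", "stage", "cumulative_percent"]].reset_index(drop=True),
                temps=temps,
                first_adult_day=first_adult,
            )
        )
    return out


def write_survey_csv(surveys: list[FieldSurvey], path) -> None:
    frames = []
    for s in surveys:
        sub = s.data.copy()
        sub.insert(0, "year", s.year)
        sub.insert(0, "site", s.site)
        if s.first_adult_day is not None:
            sub["first_adult_day"] = s.first_adult_day
        frames.append(sub)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
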