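"""Goodness-of-fit metrics between a simulated trajectory and a survey.

The survey is the reference: metrics summarize how well the model curve
tracks the observed cumulative emergence of each nymphal instar, plus
the error in the onset (first 1%) date.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibrate import FieldSurvey, _STAGE_INDEX, NYMPH_STAGES
from .kolmogorov import EmergenceTrajectory, cumulative_emergence_at

__all__ = ["evaluate_fit"]


def _onset_day(dates: np.ndarray, pct: np.ndarray, level: float = 1.0):
    idx = np.nonzero(pct >= level)[0]
    return float(dates[idx[0]]) if len(idx) else None


def evaluate_fit(sim: EmergenceTrajectory, obs: FieldSurvey) -> pd.DataFrame:
    """Per-stage RMSE/MAE (%) and onset-date error (days, sim − obs).

    Only survey dates inside the trajectory horizon are compared; raises
    if the date ranges do not overlap.
    """
    rows = []
    any_overlap = False
    for stage in NYMPH_STAGES:
        curve = obs.percent_curve(stage)
        curve = curve[curve.index <= sim.days[-1] + 1e-9]
        if curve.empty:
            continue
        any_overlap = True
        dates = curve.index.to_numpy(dtype=float)
        o = curve.to_numpy()
        s = cumulative_emergence_at(sim, _STAGE_INDEX[stage], dates)
        err = s - o
        obs_onset = _onset_day(dates, o)
        sim_onset = sim.emergence_date(_STAGE_INDEX[stage], 1.0)
        onset_err = (
            sim_onset - obs_onset if (obs_onset is not None and sim_onset is not None) else np.nan
        )
        rows.append(
            {
                "stage": stage,
                "rmse": float(np.sqrt(np.mean(err**2))),
                "mae": float(np.mean(np.abs(err))),
                "onset_error_days": onset_err,
                "n_dates": len(dates),
            }
        )
    if not any_overlap:
        raise ValueError("no survey dates fall within the simulated horizon")
    return pd.DataFrame(rows)
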