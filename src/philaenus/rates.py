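"""Temperature-dependent development-rate functions.

Development of each preimaginal stage of *Philaenus spumarius* (the
post-diapausing egg and the five nymphal instars N1-N5) is driven by air
temperature through a Brière rate function

    v(T) = a * T * (T - t_inf) * sqrt(t_sup - T)   for t_inf <= T <= t_sup,
    v(T) = 0                                       otherwise,

where ``v`` is the fraction of within-stage development completed per day,
``t_inf`` and ``t_sup`` are the lower and upper development thresholds (°C)
and ``a`` is an empirical scale constant.  The function is hump-shaped:
zero at both thresholds with a single interior optimum whose location
depends only on the thresholds, not on ``a``.

Because published parameter tables usually report the *maximum* rate rather
than the raw scale constant, :func:`scale_from_max` reconstructs ``a`` from
the peak rate and the thresholds.  Two named presets are bundled:

``parameterized``
    Chamber-derived rates (constant-temperature cohort experiments).
``calibrated``
    Field-refined rates (weekly nymphal surveys in olive groves).

Values not individually published are interpolated from the published
per-stage bounds and flagged in the preset file and in the docs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "BriereParams",
    "StageParamSet",
    "STAGE_NAMES",
    "briere_rate",
    "briere_optimum",
    "scale_from_max",
    "load_preset",
    "load_param_file",
    "available_presets",
]

#: Stage names in developmental order.  Index i = 1..7 follows the model's
#: stage numbering: 1 = post-diapausing egg, 2-6 = nymphal instars N1-N5,
#: 7 = adult (no rate function; pure accumulator).
STAGE_NAMES = ("egg", "n1", "n2", "n3", "n4", "n5")


@dataclass(frozen=True)
class BriereParams:
    """Brière rate-function parameters for one stage.

    Parameters
    ----------
    a : float
        Empirical scale constant (day^-1 · °C^-2 · °C^-1/2), > 0.
    t_inf : float
        Lower development threshold (°C).
    t_sup : float
        Upper development threshold (°C); must exceed ``t_inf``.
    """

    a: float
    t_inf: float
    t_sup: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"scale constant a must be > 0, got {self.a}")
        if not self.t_inf < self.t_sup:
            raise ValueError(
                f"thresholds must satisfy t_inf < t_sup, got "
                f"({self.t_inf}, {self.t_sup})"
            )

    @classmethod
    def from_max_rate(cls, v_max: float, t_inf: float, t_sup: float) -> "BriereParams":
        """Build parameters from the peak rate instead of the raw constant."""
        return cls(scale_from_max(v_max, t_inf, t_sup), t_inf, t_sup)

    @property
    def optimum(self) -> float:
        """Temperature (°C) at which the rate peaks."""
        return briere_optimum(self)

    @property
    def max_rate(self) -> float:
        """Peak development rate (day^-1)."""
        return float(briere_rate(self.optimum, self))


@dataclass(frozen=True)
class StageParamSet:
    """Ordered Brière parameters for stages 1 (egg) through 6 (N5).

    The adult stage (7) carries no rate function: adults only accumulate
    the flux leaving the fifth instar.
    """

    stages: tuple[BriereParams, ...]

    def __post_init__(self) -> None:
        if len(self.stages) != 6:
            raise ValueError(
                f"expected 6 stage parameter sets (egg + N1..N5), got {len(self.stages)}"
            )

    def __iter__(self) -> Iterator[BriereParams]:
        return iter(self.stages)

    def __getitem__(self, i: int) -> BriereParams:
        return self.stages[i]

    @classmethod
    def from_sequence(cls, params: Sequence[BriereParams]) -> "StageParamSet":
        return cls(tuple(params))

    def rates(self, temp: float) -> np.ndarray:
        """Development rates of all six stages at ``temp`` (shape (6,))."""
        return np.array([briere_rate(temp, p) for p in self.stages])

    @property
    def max_rate(self) -> float:
        """Largest peak rate across stages (sets the CFL time step)."""
        return max(p.max_rate for p in self.stages)

    def to_dict(self) -> dict:
        return {
            name: {"v_max": p.max_rate, "t_inf": p.t_inf, "t_sup": p.t_sup}
            for name, p in zip(STAGE_NAMES, self.stages)
        }


def briere_rate(temp, params: BriereParams):
    """Brière development rate at temperature ``temp`` (°C).

    Accepts scalars or numpy arrays; zero outside [t_inf, t_sup] and
    clamped at zero from below (development cannot run backwards).
    """
    t = np.asarray(temp, dtype=float)
    inside = (t >= params.t_inf) & (t <= params.t_sup)
    rate = np.zeros_like(t)
    ti = t[inside]
    rate[inside] = params.a * ti * (ti - params.t_inf) * np.sqrt(params.t_sup - ti)
    rate = np.maximum(rate, 0.0)
    if np.isscalar(temp) or np.ndim(temp) == 0:
        return float(rate)
    return rate


def briere_optimum(params: BriereParams) -> float:
    """Temperature maximizing the Brière rate, from the closed form.

    Setting d/dT [T (T - t_inf) sqrt(t_sup - T)] = 0 gives the quadratic
    5 T^2 - (4 t_sup + 3 t_inf) T + 2 t_inf t_sup = 0; the optimum is its
    larger root, which always lies in (t_inf, t_sup).
    """
    b = 4.0 * params.t_sup + 3.0 * params.t_inf
    disc = b * b - 40.0 * params.t_inf * params.t_sup
    return (b + math.sqrt(disc)) / 10.0


def scale_from_max(v_max: float, t_inf: float, t_sup: float) -> float:
    """Scale constant ``a`` such that the rate peaks at ``v_max``.

    Inverse of evaluating the Brière curve at its optimum:
    a = v_max / [T_opt (T_opt - t_inf) sqrt(t_sup - T_opt)].
    """
    if not v_max > 0:
        raise ValueError(f"v_max must be > 0, got {v_max}")
    if not t_inf < t_sup:
        raise ValueError(f"thresholds must satisfy t_inf < t_sup, got ({t_inf}, {t_sup})")
    probe = BriereParams(a=1.0, t_inf=t_inf, t_sup=t_sup)
    t_opt = briere_optimum(probe)
    unit_peak = briere_rate(t_opt, probe)
    return v_max / unit_peak


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _params_from_entry(entry: dict) -> BriereParams:
    t_inf = float(entry["t_inf"])
    t_sup = float(entry["t_sup"])
    if "a" in entry:
        return BriereParams(float(entry["a"]), t_inf, t_sup)
    return BriereParams.from_max_rate(float(entry["v_max"]), t_inf, t_sup)


def _stage_set_from_mapping(mapping: dict) -> StageParamSet:
    missing = [n for n in STAGE_NAMES if n not in mapping]
    if missing:
        raise KeyError(f"preset missing stages: {missing}")
    return StageParamSet(tuple(_params_from_entry(mapping[n]) for n in STAGE_NAMES))


def _load_preset_file() -> dict:
    text = resources.files("philaenus.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    return [k for k in _load_preset_file() if k not in ("diapause", "age_distribution")]


def load_preset(name: str) -> StageParamSet:
    """Load a bundled named parameter preset ('parameterized' or 'calibrated')."""
    data = _load_preset_file()
    if name not in data or name in ("diapause", "age_distribution"):
        raise KeyError(
            f"unknown preset {name!r}; available: {available_presets()}"
        )
    return _stage_set_from_mapping(data[name]["stages"])


def load_param_file(path) -> StageParamSet:
    """Load stage parameters from a user YAML file.

    Each stage entry gives ``t_inf``, ``t_sup`` and either the raw scale
    constant ``a`` or the peak rate ``v_max`` (converted at load time).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    mapping = data.get("stages", data)
    return _stage_set_from_mapping(mapping)
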