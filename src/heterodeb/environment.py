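"""Synthetic winter environment: snow depth, forage accessibility, body temperature.

The simulation window runs 1 October - 31 May (243 days in a non-leap
spring).  Snow depth stands in for a multi-year mean of modeled snow over a
high-Arctic tundra valley: a smooth unimodal curve from bare ground in
October to a late-winter maximum (88 cm by default) followed by spring melt.
Forage accessibility is a scaled functional response f in [0, 1] that
declines linearly with snow depth, anchored so 88 cm of snow gives f = 0.70,
with no cutoff depth.

Group body-temperature profiles represent two overwintering strategies:
normotherms hold a constant winter mean (38.2 C) while heterotherms diverge
from the normotherm level on 1 October by a ramp whose depth is solved so
the overwinter mean hits a configured target (37.4 C).  Individual daily
variation is added by a log-normal scatter multiplier; see
:func:`apply_scatter` for the two application modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SEASON_KINDS",
    "DailySeries",
    "ScatterConfig",
    "TBProfileConfig",
    "simulation_window",
    "generate_snow_series",
    "snow_to_functional_response",
    "scale_accessibility",
    "generate_tb_profile",
    "scatter_multiplier",
    "apply_scatter",
    "read_daily_series",
    "write_daily_series",
]

SEASON_KINDS = ("snow_cm", "tb_celsius", "f_scaled")

#: slope of the snow -> functional-response mapping: f falls by 0.30 over
#: the calibration depth of 88 cm (f(88 cm) = 0.70), with floor 0.
F_SLOPE_PER_CM = 0.30 / 88.0

#: hard sanity bounds on plausible ungulate body temperature [C]
TB_BOUNDS = (30.0, 42.0)


def simulation_window(start_year: int = 2000) -> pd.DatetimeIndex:
    """Daily index 1 Oct ``start_year`` - 31 May of the following year.

    The default season (2000/2001) has a non-leap February, giving the
    canonical 243-day window.
    """
    return pd.date_range(f"{start_year}-10-01", f"{start_year + 1}-05-31",
                         freq="D")


@dataclass
class DailySeries:
    """A dated daily sequence over the simulation window."""

    values: np.ndarray
    dates: pd.DatetimeIndex
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SEASON_KINDS:
            raise ValueError(f"kind must be one of {SEASON_KINDS}, got {self.kind!r}")
        if len(self.values) != len(self.dates):
            raise ValueError("values and dates must have equal length")
        if not (self.dates.to_series().diff().dropna() == pd.Timedelta("1D")).all():
            raise ValueError("dates must be consecutive daily values")
        if self.kind == "snow_cm" and np.any(self.values < 0.0):
            raise ValueError("snow depth cannot be negative")
        if self.kind == "f_scaled" and np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("functional response must lie in [0, 1]")
        if self.kind == "tb_celsius" and np.any(
                (self.values <= TB_BOUNDS[0]) | (self.values >= TB_BOUNDS[1])):
            raise ValueError(f"body temperature outside sanity bounds {TB_BOUNDS}")

    def __len__(self) -> int:
        return len(self.values)

    def copy_with(self, values: np.ndarray, kind: Optional[str] = None) -> "DailySeries":
        return DailySeries(values=np.asarray(values, dtype=float),
                           dates=self.dates, kind=kind or self.kind)


@dataclass
class ScatterConfig:
    """Individual daily body-temperature scatter.

    ``cv`` is the coefficient of variation of the log-normal scatter
    multiplier exp(N(0, cv)).  In ``multiplicative`` mode the multiplier is
    applied to TB in C with a mean-preserving bias correction; in
    ``additive`` mode (default) the same cv is read as the standard
    deviation of a mean-zero daily deviation in C, which keeps daily
    excursions at the sub-degree scale actually observed in large ungulates.
    """

    cv_normotherm: float = 0.10
    cv_heterotherm: float = 0.15
    mode: Literal["additive", "multiplicative"] = "additive"

    def __post_init__(self) -> None:
        if self.cv_normotherm < 0 or self.cv_heterotherm < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown scatter mode {self.mode!r}")

    def cv_for(self, group: str) -> float:
        return {"normotherm": self.cv_normotherm,
                "heterotherm": self.cv_heterotherm}[group]


@dataclass
class TBProfileConfig:
    """Group mean body-temperature trajectories [C].

    The heterotherm ramp is linear from the normotherm level on 1 Oct down
    to its trough and (optionally) linearly back toward the normotherm
    level; ``trough_frac`` places the trough as a fraction of the window
    (1.0 = last day, i.e. divergence grows all winter) and
    ``recovery_frac`` sets how much of the maximal drop is recovered by
    31 May.  The ramp depth is solved so the heterotherm overwinter mean
    equals ``heterotherm_mean``.
    """

    normotherm_mean: float = 38.2
    heterotherm_mean: float = 37.4
    trough_frac: float = 1.0
    recovery_frac: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.trough_frac <= 1.0:
            raise ValueError("trough_frac must be in (0, 1]")
        if not 0.0 <= self.recovery_frac <= 1.0:
            raise ValueError("recovery_frac must be in [0, 1]")


def generate_snow_series(
    winter_max_cm: float = 88.0,
    dates: Optional[pd.DatetimeIndex] = None,
    peak_day: int = 165,
    melt_days: int = 120,
) -> DailySeries:
    """Smooth unimodal snow curve emulating a multi-year mean winter.

    Zero depth on 1 Oct, cosine-shaped accumulation to exactly
    ``winter_max_cm`` on day ``peak_day`` (default mid-March), then a cosine
    melt over ``melt_days``.  Deterministic given its configuration.
    """
    if winter_max_cm < 0:
        raise ValueError("winter maximum snow depth cannot be negative")
    if dates is None:
        dates = simulation_window()
    t = np.arange(len(dates), dtype=float)
    accumulation = 0.5 * (1.0 - np.cos(np.pi * t / peak_day))
    melt = 0.5 * (1.0 + np.cos(np.pi * (t - peak_day) / melt_days))
    shape = np.where(t <= peak_day, accumulation, np.maximum(melt, 0.0))
    return DailySeries(values=winter_max_cm * shape, dates=dates, kind="snow_cm")


def snow_to_functional_response(depth_cm) -> np.ndarray | float | DailySeries:
    """Scaled functional response from snow depth: f = 1 - 0.30/88 * depth.

    Linear with floor zero and no access-cutoff depth; f(0) = 1 and
    f(88 cm) = 0.70.
    """
    if isinstance(depth_cm, DailySeries):
        values = snow_to_functional_response(depth_cm.values)
        return depth_cm.copy_with(values, kind="f_scaled")
    depth = np.asarray(depth_cm, dtype=float)
    if np.any(depth < 0.0):
        raise ValueError("snow depth cannot be negative")
    f = np.maximum(0.0, 1.0 - F_SLOPE_PER_CM * depth)
    return f if f.ndim else float(f)


def scale_accessibility(f_series, factor: float):
    """Multiply daily functional-response values by ``factor``, clamped to [0, 1]."""
    if not factor > 0:
        raise ValueError("accessibility factor must be positive")
    if isinstance(f_series, DailySeries):
        return f_series.copy_with(np.clip(f_series.values * factor, 0.0, 1.0))
    return np.clip(np.asarray(f_series, dtype=float) * factor, 0.0, 1.0)


def heterotherm_ramp_shape(n_days: int, config: TBProfileConfig) -> np.ndarray:
    """Unit-depth divergence shape s(t): 0 on day 0, 1 at the trough."""
    t = np.arange(n_days, dtype=float)
    trough = config.trough_frac * (n_days - 1)
    shape = np.where(t <= trough, t / trough, 1.0)
    if config.recovery_frac > 0 and trough < n_days - 1:
        rec = (t - trough) / (n_days - 1 - trough)
        shape = np.where(t > trough, 1.0 - config.recovery_frac * rec, shape)
    return shape


def generate_tb_profile(
    group: str,
    config: Optional[TBProfileConfig] = None,
    dates: Optional[pd.DatetimeIndex] = None,
) -> DailySeries:
    """Group-mean daily body temperature for one overwinter strategy.

    Normotherms hold ``normotherm_mean`` all winter.  Heterotherms start at
    the normotherm level on 1 Oct and follow the configured divergence ramp,
    whose depth is solved exactly so the overwinter mean equals
    ``heterotherm_mean``.
    """
    config = config or TBProfileConfig()
    if dates is None:
        dates = simulation_window()
    n = len(dates)
    if group == "normotherm":
        values = np.full(n, config.normotherm_mean)
    elif group == "heterotherm":
        shape = heterotherm_ramp_shape(n, config)
        mean_drop = config.normotherm_mean - config.heterotherm_mean
        if mean_drop < 0:
            raise ValueError("heterotherm mean cannot exceed the normotherm mean")
        depth = mean_drop / shape.mean()
        values = config.normotherm_mean - depth * shape
        if values.min() <= TB_BOUNDS[0]:
            raise ValueError(
                "infeasible mean/shape combination: ramp depth "
                f"{depth:.2f} C pushes TB below {TB_BOUNDS[0]} C")
        assert abs(values.mean() - config.heterotherm_mean) < 0.01
    else:
        raise ValueError(f"unknown group {group!r}")
    return DailySeries(values=values, dates=dates, kind="tb_celsius")


def scatter_multiplier(cv: float, rng: np.random.Generator, size=None):
    """Log-normal scatter multiplier exp(N(0, cv)); median exactly 1."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    return np.exp(rng.normal(0.0, cv, size=size))


def apply_scatter(
    tb_mean,
    cv: float,
    rng: np.random.Generator,
    mode: str = "additive",
    size=None,
):
    """Individual daily body temperature around the group mean [C].

    ``multiplicative``: TB * m / exp(cv^2 / 2) with m the log-normal scatter
    multiplier; the divisor is the mean-preserving bias correction (the raw
    multiplier has mean exp(cv^2/2), not 1).  ``additive``: TB + N(0, cv)
    with cv read as a standard deviation in C.  Both modes leave the
    expected scattered TB equal to the group mean.
    """
    tb = np.asarray(tb_mean, dtype=float)
    if mode == "multiplicative":
        return tb * scatter_multiplier(cv, rng, size=size) / np.exp(cv ** 2 / 2.0)
    if mode == "additive":
        return tb + rng.normal(0.0, cv, size=size)
    raise ValueError(f"unknown scatter mode {mode!r}")


def write_daily_series(series: DailySeries, path: str | Path) -> None:
    """Write a two-column ``date,value`` CSV (ISO dates, header row)."""
    frame = pd.DataFrame({"date": series.dates.strftime("%Y-%m-%d"),
                          "value": series.values})
    frame.to_csv(path, index=False)


def read_daily_series(path: str | Path, kind: str) -> DailySeries:
    """Read a ``date,value`` CSV; gaps or duplicate dates raise with the dates."""
    frame = pd.read_csv(path, parse_dates=["date"])
    if list(frame.columns) != ["date", "value"]:
        raise ValueError(f"{path}: expected header 'date,value', "
                         f"got {list(frame.columns)}")
    dates = pd.DatetimeIndex(frame["date"])
    duplicated = dates[dates.duplicated()].unique()
    if len(duplicated):
        raise ValueError(f"{path}: duplicate date(s): "
                         + ", ".join(d.strftime("%Y-%m-%d") for d in duplicated))
    expected = pd.date_range(dates.min(), dates.max(), freq="D")
    missing = expected.difference(dates)
    if len(missing):
        raise ValueError(f"{path}: missing date(s): "
                         + ", ".join(d.strftime("%Y-%m-%d") for d in missing))
    return DailySeries(values=frame["value"].to_numpy(dtype=float),
                       dates=dates, kind=kind)
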