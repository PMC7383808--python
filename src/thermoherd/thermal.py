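"""Temperature–humidity index (THI) and the broken-stick heat-load covariate.

The THI combines dry-bulb temperature and relative humidity into a single
heat-load scalar.  Conception is assumed unaffected below a threshold THI
(default 68); above it, performance declines linearly, so the reaction-norm
regressor attached to each insemination is ``f(THI) = max(0, THI - 68)``
evaluated at the daily mean THI of the insemination date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ThermalConfig",
    "thi",
    "daily_mean_thi",
    "heat_load",
    "read_weather",
    "daily_thi_table",
    "attach_heat_load",
]


@dataclass(frozen=True)
class ThermalConfig:
    """Settings for the heat-load covariate.

    Parameters
    ----------
    thi_threshold : float
        THI value below which no heat stress is assumed (broken-stick knot).
    min_hours_per_day : int
        Minimum number of hourly records required to form a daily mean THI;
        days with fewer hours are dropped (no imputation).
    """

    thi_threshold: float = 68.0
    min_hours_per_day: int = 1

    def __post_init__(self) -> None:
        if self.thi_threshold <= 0:
            raise ValueError("thi_threshold must be positive")
        if self.min_hours_per_day < 1:
            raise ValueError("min_hours_per_day must be >= 1")


def thi(temp, rh):
    """Temperature–humidity index from °C temperature and % relative humidity.

    ``THI = (1.8*temp + 32) - (0.55 - 0.0055*rh) * (1.8*temp - 26)``

    Accepts scalars or arrays; relative humidity must lie in [0, 100].
    """
    temp = np.asarray(temp, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity must be within [0, 100] percent")
    out = (1.8 * temp + 32.0) - (0.55 - 0.0055 * rh) * (1.8 * temp - 26.0)
    return out if out.ndim else float(out)


def daily_mean_thi(records) -> float:
    """Arithmetic mean of hourly THI values for one calendar date.

    ``records`` is a DataFrame (columns ``temp_c``, ``rh_pct``) or a sequence
    of ``(temp, rh)`` pairs, all belonging to the same date.
    """
    if isinstance(records, pd.DataFrame):
        if len(records) == 0:
            raise ValueError("no weather records for the date")
        vals = thi(records["temp_c"].to_numpy(), records["rh_pct"].to_numpy())
    else:
        pairs = list(records)
        if not pairs:
            raise ValueError("no weather records for the date")
        vals = np.array([thi(t, r) for t, r in pairs])
    return float(np.mean(vals))


def heat_load(thi_value, config: ThermalConfig | float = ThermalConfig()):
    """Broken-stick heat load ``f(THI) = max(0, THI - threshold)``.

    ``config`` may be a :class:`ThermalConfig` or a bare threshold value.
    """
    thr = config.thi_threshold if isinstance(config, ThermalConfig) else float(config)
    thi_value = np.asarray(thi_value, dtype=float)
    out = np.maximum(0.0, thi_value - thr)
    return out if out.ndim else float(out)


def read_weather(path) -> pd.DataFrame:
    """Read an hourly weather CSV: date (ISO 8601), hour, temp_c, rh_pct.

    An optional ``station`` column is carried through for joins against herds
    served by different weather stations.
    """
    df = pd.read_csv(path)
    required = {"date", "hour", "temp_c", "rh_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weather file missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["hour"] = df["hour"].astype(int)
    if ((df["hour"] < 0) | (df["hour"] > 23)).any():
        raise ValueError("hour must be in 0..23")
    if df.duplicated(subset=[c for c in ("station", "date", "hour") if c in df.columns]).any():
        raise ValueError("duplicate (date, hour) weather rows")
    return df


def daily_thi_table(weather: pd.DataFrame, config: ThermalConfig = ThermalConfig()) -> pd.DataFrame:
    """Daily mean THI per (station,) date.

    Days with fewer than ``config.min_hours_per_day`` hourly records are
    dropped with a logged warning.  Returns columns (station,) date,
    ``thi_mean``, ``n_hours``.
    """
    df = weather.copy()
    df["_thi"] = thi(df["temp_c"].to_numpy(), df["rh_pct"].to_numpy())
    keys = ["station", "date"] if "station" in df.columns else ["date"]
    grouped = df.groupby(keys, sort=True)["_thi"].agg(["mean", "size"]).reset_index()
    grouped = grouped.rename(columns={"mean": "thi_mean", "size": "n_hours"})
    short = grouped["n_hours"] < config.min_hours_per_day
    if short.any():
        logger.warning("dropping %d day(s) with < %d weather hours", int(short.sum()), config.min_hours_per_day)
        grouped = grouped.loc[~short].reset_index(drop=True)
    return grouped


def attach_heat_load(
    records: pd.DataFrame,
    daily_thi: pd.DataFrame,
    config: ThermalConfig = ThermalConfig(),
) -> pd.DataFrame:
    """Attach daily mean THI and ``f_thi`` to insemination records.

    Joins by calendar date (plus ``station`` when both tables carry it, so
    herds can be mapped to their serving weather station).  Records whose
    date has no weather are dropped with a logged warning.
    """
    keys = ["date"]
    if "station" in records.columns and "station" in daily_thi.columns:
        keys = ["station", "date"]
    out = records.merge(daily_thi[keys + ["thi_mean"]], on=keys, how="left")
    missing = out["thi_mean"].isna()
    if missing.any():
        logger.warning("dropping %d insemination record(s) with no weather for their date", int(missing.sum()))
        out = out.loc[~missing].reset_index(drop=True)
    out["f_thi"] = heat_load(out["thi_mean"].to_numpy(), config)
    return out
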