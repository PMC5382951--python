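"""Wet-bulb globe temperature from weather-station records.

The natural wet-bulb temperature is approximated from air temperature and
relative humidity with Stull's closed-form empirical fit (all arctangents
in radians — evaluating them in degrees silently produces nonsense), and
combined with the black-globe and air temperatures using the standard
outdoor weighting WBGT = 0.7·Tw + 0.2·Tg + 0.1·T.  Per night the module
locates the WBGT minimum and its time and evaluates WBGT at sleep events
with a step (latest-sample) convention on the 10-min cadence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable

import numpy as np
import pandas as pd

from .timebase_io import AnalysisNight

__all__ = [
    "DailyWbgtMin", "wet_bulb_stull", "wbgt", "wbgt_series",
    "daily_min", "wbgt_at", "event_wbgt_deltas",
]

WBGT_WEIGHTS = (0.7, 0.2, 0.1)  # natural wet-bulb, black globe, dry air

# stated validity of the closed-form fit
_RH_VALID = (5.0, 99.0)
_T_VALID = (-20.0, 50.0)


@dataclass(frozen=True)
class DailyWbgtMin:
    night: AnalysisNight
    wbgt_min_c: float
    time_of_min: datetime


def wet_bulb_stull(T, RH):
    """Natural wet-bulb temperature (°C) from air temperature and RH%.

    Accepts scalars or arrays.  RH outside [0, 100] is an input error;
    values outside the fit's stated validity range (RH 5–99 %, T −20–50 °C)
    trigger a warning but are still computed.
    """
    T = np.asarray(T, dtype=float)
    RH = np.asarray(RH, dtype=float)
    if np.any(RH < 0) or np.any(RH > 100):
        raise ValueError("relative humidity must be within [0, 100] %")
    if (np.any(RH < _RH_VALID[0]) or np.any(RH > _RH_VALID[1])
            or np.any(T < _T_VALID[0]) or np.any(T > _T_VALID[1])):
        warnings.warn("input outside the wet-bulb fit's stated validity range",
                      stacklevel=2)
    tw = (
        T * np.arctan(0.151977 * np.sqrt(RH + 8.313659))
        + np.arctan(T + RH)
        - np.arctan(RH - 1.676331)
        + 0.00391838 * RH ** 1.5 * np.arctan(0.023101 * RH)
        - 4.686035
    )
    return tw if tw.ndim else float(tw)


def wbgt(tw, tg, t):
    """Outdoor wet-bulb globe temperature: 0.7·Tw + 0.2·Tg + 0.1·T (°C)."""
    w_tw, w_tg, w_t = WBGT_WEIGHTS
    out = w_tw * np.asarray(tw, float) + w_tg * np.asarray(tg, float) \
        + w_t * np.asarray(t, float)
    return out if out.ndim else float(out)


def wbgt_series(weather: pd.DataFrame) -> pd.DataFrame:
    """Append natural wet-bulb (``tw_c``) and ``wbgt_c`` columns."""
    out = weather.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # field data may brush the validity edge
        out["tw_c"] = wet_bulb_stull(out["air_c"].to_numpy(),
                                     out["rh_pct"].to_numpy())
    out["wbgt_c"] = wbgt(out["tw_c"], out["globe_c"], out["air_c"])
    return out


def daily_min(env: pd.DataFrame, night: AnalysisNight) -> DailyWbgtMin:
    """Minimum WBGT and its sample time within the full night window.

    The earliest sample wins ties, so constant weather pins the minimum to
    the first sample of the window.
    """
    ts = pd.to_datetime(env["timestamp"])
    mask = (ts >= night.window_start) & (ts < night.window_end)
    sub = env.loc[mask.to_numpy()]
    if sub.empty:
        raise ValueError(f"no weather samples in night {night.label_date}")
    values = sub["wbgt_c"].to_numpy()
    i = int(np.argmin(values))  # argmin returns the earliest of equal minima
    return DailyWbgtMin(
        night=night,
        wbgt_min_c=float(values[i]),
        time_of_min=ts[mask].iloc[i].to_pydatetime(),
    )


def wbgt_at(env: pd.DataFrame, t: datetime) -> float:
    """WBGT at time ``t`` using the value of the latest sample ≤ t."""
    ts = pd.to_datetime(env["timestamp"])
    mask = ts <= t
    if not mask.any():
        raise ValueError(f"{t} precedes weather coverage")
    last = mask[mask].index[-1]
    if t - ts[last] > pd.Timedelta(minutes=10):
        raise ValueError(f"{t} is beyond weather coverage")
    return float(env.loc[last, "wbgt_c"])


def event_wbgt_deltas(nights: Iterable[tuple[AnalysisNight, datetime | None, datetime | None]],
                      env: pd.DataFrame) -> pd.DataFrame:
    """Per-night WBGT context of sleep onset and offset.

    ``nights`` yields (night, onset, offset) with None for undefined
    events.  Returns one row per night with the WBGT minimum, the signed
    excess of onset/offset WBGT over the minimum (°C), and the signed
    offsets of the events from the time of minimum (minutes, negative =
    before the minimum).
    """
    rows = []
    for night, onset, offset in nights:
        dm = daily_min(env, night)
        row = {
            "night": night.label_date,
            "wbgt_min_c": dm.wbgt_min_c,
            "time_of_min": dm.time_of_min,
            "onset_excess_c": np.nan, "offset_excess_c": np.nan,
            "onset_rel_min": np.nan, "offset_rel_min": np.nan,
        }
        if onset is not None:
            row["onset_excess_c"] = wbgt_at(env, onset) - dm.wbgt_min_c
            row["onset_rel_min"] = (onset - dm.time_of_min).total_seconds() / 60.0
        if offset is not None:
            row["offset_excess_c"] = wbgt_at(env, offset) - dm.wbgt_min_c
            row["offset_rel_min"] = (offset - dm.time_of_min).total_seconds() / 60.0
        rows.append(row)
    return pd.DataFrame(rows)
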