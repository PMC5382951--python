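"""Behavioural-sleep scoring from 1-min trunk-actigraphy counts.

The trunk is an obligate instrument of waking behaviour, so a completely
immobile trunk is taken as the behavioural proxy for sleep: 1-min epochs
are scored active when the count exceeds a threshold (default: any count
above zero), five consecutive epochs are collapsed to their modal state,
and maximal runs of inactive 5-min blocks become sleep episodes.  Per
night (noon-to-noon, labelled by the morning date) the module derives
total sleep time, the main (longest) episode, consolidated onset/offset
relative to sunset/sunrise, and a no-sleep flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .timebase_io import AnalysisNight, AstroDay

__all__ = [
    "SleepEpisode",
    "NightSleepSummary",
    "score_epochs",
    "aggregate_modal",
    "detect_episodes",
    "detect_onset",
    "detect_offset",
    "classify_no_sleep",
    "night_summary",
    "nocturnality",
]

BLOCK_MIN = 5
#: a *consolidated* episode must exceed 10 min; at 5-min granularity that
#: means at least 3 blocks (15 min), since 10 min is not > 10
CONSOLIDATED_MIN = 15
#: total nightly inactivity at or below this many minutes counts as no sleep
NO_SLEEP_MAX_MIN = 10


@dataclass(frozen=True)
class SleepEpisode:
    """A maximal run of inactive 5-min blocks."""

    start: datetime
    end: datetime
    is_main: bool = False

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    def overlaps_night(self, night: AnalysisNight) -> bool:
        return self.start < night.window_end and self.end > night.window_start


@dataclass(frozen=True)
class NightSleepSummary:
    night: AnalysisNight
    tst_h: float
    n_episodes: int
    main_episode_h: float
    mean_other_episode_min: float
    onset: datetime | None
    offset: datetime | None
    no_sleep: bool
    nocturnal_fraction: float


def score_epochs(actigraphy: pd.DataFrame, active_threshold: int = 0) -> pd.Series:
    """Score 1-min epochs as active (count > threshold) or inactive.

    Returns a boolean Series (True = active) indexed by timestamp.
    Raises ``ValueError`` when the cadence is not 60 s.
    """
    ts = pd.to_datetime(actigraphy["timestamp"])
    if len(ts) > 1:
        steps = ts.diff().dropna().dt.total_seconds()
        if not (steps == 60).all():
            raise ValueError("actigraphy cadence must be exactly 60 s")
    counts = actigraphy["count"].to_numpy()
    if (counts < 0).any():
        raise ValueError("activity counts must be non-negative")
    return pd.Series(counts > active_threshold, index=ts, name="active")


def aggregate_modal(active: pd.Series, block_min: int = BLOCK_MIN) -> pd.Series:
    """Collapse 1-min active/inactive epochs to modal 5-min block states.

    Blocks are aligned to clock times divisible by ``block_min``; partial
    leading/trailing blocks are discarded.  ``block_min`` must be odd so a
    binary majority is always defined.

    Returns a boolean Series (True = inactive, i.e. behavioural sleep)
    indexed by block start.
    """
    if block_min % 2 == 0:
        raise ValueError("block_min must be odd: ties undefined for binary states")
    if active.empty:
        return pd.Series(dtype=bool, name="inactive")
    idx = active.index
    offset_min = (idx.hour * 60 + idx.minute) % block_min
    block_start = idx - pd.to_timedelta(offset_min, unit="m")
    grouped = (~active).groupby(block_start)
    full = grouped.count() == block_min
    inactive = grouped.sum() > block_min // 2
    out = inactive[full]
    out.name = "inactive"
    return out


def detect_episodes(blocks: pd.Series, night: AnalysisNight | None = None,
                    block_min: int = BLOCK_MIN) -> list[SleepEpisode]:
    """Find maximal runs of inactive blocks; flag the longest as main.

    With ``night`` given, runs are truncated at the noon window edges and
    only blocks inside the window are considered.  The earliest of
    equal-longest episodes wins the main flag.
    """
    if night is not None:
        mask = (blocks.index >= night.window_start) & (blocks.index < night.window_end)
        blocks = blocks[mask]
    if blocks.empty:
        return []
    step = timedelta(minutes=block_min)
    episodes: list[tuple[datetime, datetime]] = []
    run_start: datetime | None = None
    prev: datetime | None = None
    for t, inactive in blocks.items():
        contiguous = prev is not None and t - prev == step
        if inactive:
            if run_start is None or not contiguous:
                if run_start is not None:
                    episodes.append((run_start, prev + step))
                run_start = t
        else:
            if run_start is not None:
                episodes.append((run_start, prev + step))
                run_start = None
        prev = t
    if run_start is not None:
        episodes.append((run_start, prev + step))
    if not episodes:
        return []
    durations = [(e - s).total_seconds() for s, e in episodes]
    main_i = int(np.argmax(durations))  # argmax takes the earliest on ties
    return [
        SleepEpisode(start=s, end=e, is_main=(i == main_i))
        for i, (s, e) in enumerate(episodes)
    ]


def _sunset_in_window(astro: Mapping, night: AnalysisNight) -> datetime | None:
    """The sunset that actually falls inside the night window (evening date)."""
    evening = night.label_date - timedelta(days=1)
    day = astro.get(evening)
    if day is None:
        return None
    return datetime.combine(evening, day.sunset)


def _sunrise_in_window(astro: Mapping, night: AnalysisNight) -> datetime | None:
    day = astro.get(night.label_date)
    if day is None:
        return None
    return datetime.combine(night.label_date, day.sunrise)


def detect_onset(episodes: Sequence[SleepEpisode], astro: Mapping[object, AstroDay],
                 night: AnalysisNight) -> datetime | None:
    """Start of the first consolidated (> 10 min) episode after sunset.

    Returns None when no qualifying episode exists (propagates into the
    no-sleep handling).
    """
    sunset = _sunset_in_window(astro, night)
    if sunset is None:
        raise ValueError(f"no sunset available for night {night.label_date}")
    for ep in sorted(episodes, key=lambda e: e.start):
        if (ep.duration_min >= CONSOLIDATED_MIN and ep.start >= sunset
                and night.contains(ep.start)):
            return ep.start
    return None


def detect_offset(episodes: Sequence[SleepEpisode], astro: Mapping[object, AstroDay],
                  night: AnalysisNight) -> datetime | None:
    """End of the last consolidated (> 10 min) episode ending before sunrise."""
    sunrise = _sunrise_in_window(astro, night)
    if sunrise is None:
        raise ValueError(f"no sunrise available for night {night.label_date}")
    best: datetime | None = None
    for ep in episodes:
        if (ep.duration_min >= CONSOLIDATED_MIN and ep.end <= sunrise
                and night.contains(ep.start)):
            if best is None or ep.end > best:
                best = ep.end
    return best


def classify_no_sleep(blocks: pd.Series, night: AnalysisNight,
                      block_min: int = BLOCK_MIN) -> bool:
    """True when total nightly inactivity is at most 10 minutes.

    A night with only one or two isolated 5-min inactive blocks therefore
    counts as a night without sleep.
    """
    mask = (blocks.index >= night.window_start) & (blocks.index < night.window_end)
    inactive_min = int(blocks[mask].sum()) * block_min
    return inactive_min <= NO_SLEEP_MAX_MIN


def night_summary(episodes: Sequence[SleepEpisode], astro: Mapping[object, AstroDay],
                  night: AnalysisNight, blocks: pd.Series | None = None) -> NightSleepSummary:
    """Per-night digest: TST, episode structure, onset/offset, no-sleep flag."""
    eps = sorted((e for e in episodes if night.contains(e.start)), key=lambda e: e.start)
    total_min = sum(e.duration_min for e in eps)
    no_sleep = total_min <= NO_SLEEP_MAX_MIN
    main = max(eps, key=lambda e: e.duration_min, default=None)
    others = [e.duration_min for e in eps if e is not main]
    nocturnal = _nocturnal_fraction(eps, astro, night)
    return NightSleepSummary(
        night=night,
        tst_h=total_min / 60.0,
        n_episodes=len(eps),
        main_episode_h=(main.duration_min / 60.0) if main else 0.0,
        mean_other_episode_min=float(np.mean(others)) if others else 0.0,
        onset=detect_onset(eps, astro, night),
        offset=detect_offset(eps, astro, night),
        no_sleep=no_sleep,
        nocturnal_fraction=nocturnal,
    )


def _nocturnal_fraction(episodes: Sequence[SleepEpisode], astro, night,
                        block_min: int = BLOCK_MIN) -> float:
    sunset = _sunset_in_window(astro, night)
    sunrise = _sunrise_in_window(astro, night)
    if sunset is None or sunrise is None:
        return float("nan")
    total = night_blocks = 0
    for ep in episodes:
        t = ep.start
        while t < ep.end:
            total += 1
            if sunset <= t < sunrise:
                night_blocks += 1
            t += timedelta(minutes=block_min)
    return night_blocks / total if total else float("nan")


def nocturnality(blocks: pd.Series, astro: Mapping[object, AstroDay],
                 nights: Sequence[AnalysisNight], block_min: int = BLOCK_MIN) -> float:
    """Fraction of inactive 5-min blocks falling between sunset and sunrise.

    Computed over a whole deployment (a sequence of analysis nights).
    """
    total = dark = 0
    for night in nights:
        sunset = _sunset_in_window(astro, night)
        sunrise = _sunrise_in_window(astro, night)
        mask = (blocks.index >= night.window_start) & (blocks.index < night.window_end)
        for t, inactive in blocks[mask].items():
            if not inactive:
                continue
            total += 1
            if sunset is not None and sunrise is not None and sunset <= t < sunrise:
                dark += 1
    return dark / total if total else float("nan")
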