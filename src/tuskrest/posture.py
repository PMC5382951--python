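"""Standing / recumbent posture from collar tri-axial accelerometry.

When the collar is not accelerating the resultant of the three axes sits
at 1 g (within ±0.1 g) and the gravity direction identifies posture: a
positive vertical (Z) component means standing, a negative one lying
down, with the lying side read from the sign of the transverse (X)
component when it carries close to the full 1 g.  Classified samples are
run-length encoded into bouts and intersected with the behavioural sleep
blocks to give per-night recumbent-sleep statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .sleep_scoring import BLOCK_MIN, SleepEpisode
from .timebase_io import AnalysisNight

__all__ = [
    "STANDING", "LYING_LEFT", "LYING_RIGHT", "LYING_UNSIDED", "INDETERMINATE",
    "PostureBout", "RecumbencyNightStats",
    "resultant", "classify_posture", "classify_samples", "posture_bouts",
    "recumbent_sleep", "recumbency_gap_run",
]

STANDING = "standing"
LYING_LEFT = "lying_left"
LYING_RIGHT = "lying_right"
LYING_UNSIDED = "lying"
INDETERMINATE = "indeterminate"

LYING_POSTURES = frozenset({LYING_LEFT, LYING_RIGHT, LYING_UNSIDED})

RESULTANT_TOL = 0.1   # |r - 1 g| window for a non-accelerating collar
LATERAL_TOL = 0.3     # |X| within this of 1 g asserts the lying side
BRIDGE_MAX_MIN = 2    # indeterminate gap bridged inside a bout


@dataclass(frozen=True)
class PostureBout:
    start: datetime
    end: datetime
    posture: str

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass(frozen=True)
class RecumbencyNightStats:
    night: AnalysisNight
    recumbent_sleep_min: float
    n_episodes: int
    left_min: float
    right_min: float


def resultant(ax: float, ay: float, az: float) -> float:
    """Euclidean norm of the three axis accelerations, in g."""
    return math.sqrt(ax * ax + ay * ay + az * az)


def classify_posture(ax: float, ay: float, az: float,
                     tol: float = RESULTANT_TOL,
                     lateral_tol: float = LATERAL_TOL) -> str:
    """Classify one sample as standing / lying (left/right) / indeterminate.

    Indeterminate when the resultant is outside 1 ± ``tol`` g (the collar
    is accelerating).  Standing when Z > 0; otherwise lying, with the side
    asserted only when |X| is within ``lateral_tol`` of 1 g.
    """
    r = resultant(ax, ay, az)
    if abs(r - 1.0) > tol:
        return INDETERMINATE
    if az > 0:
        return STANDING
    if abs(abs(ax) - 1.0) <= lateral_tol:
        return LYING_RIGHT if ax > 0 else LYING_LEFT
    return LYING_UNSIDED


def classify_samples(accel: pd.DataFrame, tol: float = RESULTANT_TOL,
                     lateral_tol: float = LATERAL_TOL) -> pd.Series:
    """Vectorised classification of an accel stream (timestamp-indexed)."""
    ax = accel["ax_g"].to_numpy(float)
    ay = accel["ay_g"].to_numpy(float)
    az = accel["az_g"].to_numpy(float)
    r = np.sqrt(ax * ax + ay * ay + az * az)
    out = np.full(len(ax), INDETERMINATE, dtype=object)
    still = np.abs(r - 1.0) <= tol
    out[still & (az > 0)] = STANDING
    lying = still & (az <= 0)
    sided = lying & (np.abs(np.abs(ax) - 1.0) <= lateral_tol)
    out[lying] = LYING_UNSIDED
    out[sided & (ax > 0)] = LYING_RIGHT
    out[sided & (ax < 0)] = LYING_LEFT
    return pd.Series(out, index=pd.to_datetime(accel["timestamp"]), name="posture")


def posture_bouts(postures: pd.Series, min_bout_min: float = 1.0,
                  bridge_max_min: float = BRIDGE_MAX_MIN) -> list[PostureBout]:
    """Run-length encode classified 1-min samples into posture bouts.

    Indeterminate samples inherit the surrounding posture when flanked by
    identical postures and the gap is at most ``bridge_max_min`` minutes;
    longer indeterminate runs split the bout.
    """
    if postures.empty:
        return []
    times = postures.index
    values = list(postures.to_numpy(object))

    # bridge short indeterminate runs flanked by the same posture
    n = len(values)
    i = 0
    while i < n:
        if values[i] == INDETERMINATE:
            j = i
            while j < n and values[j] == INDETERMINATE:
                j += 1
            run_len = j - i
            if (0 < i and j < n and values[i - 1] == values[j]
                    and values[i - 1] != INDETERMINATE
                    and run_len <= bridge_max_min):
                for k in range(i, j):
                    values[k] = values[i - 1]
            i = j
        else:
            i += 1

    bouts: list[PostureBout] = []
    step = timedelta(minutes=1)
    run_start = None
    run_posture = None
    prev_t = None
    for t, p in zip(times, values):
        contiguous = prev_t is not None and t - prev_t == step
        if p != run_posture or not contiguous:
            if run_posture not in (None, INDETERMINATE):
                bouts.append(PostureBout(run_start, prev_t + step, run_posture))
            run_start, run_posture = t, p
        prev_t = t
    if run_posture not in (None, INDETERMINATE):
        bouts.append(PostureBout(run_start, prev_t + step, run_posture))
    return [b for b in bouts if b.duration_min >= min_bout_min]


def _overlap_min(a0: datetime, a1: datetime, b0: datetime, b1: datetime) -> float:
    lo, hi = max(a0, b0), min(a1, b1)
    return max(0.0, (hi - lo).total_seconds() / 60.0)


def recumbent_sleep(bouts: Sequence[PostureBout], episodes: Sequence[SleepEpisode],
                    night: AnalysisNight, episode_gap_min: float = BLOCK_MIN,
                    ) -> RecumbencyNightStats:
    """Intersect lying bouts with sleep episodes within one night.

    Recumbent-sleep minutes are the total interval intersection; intersected
    runs separated by at least ``episode_gap_min`` minutes of
    non-recumbent-sleep count as distinct episodes.
    """
    w0, w1 = night.window_start, night.window_end
    intervals: list[tuple[datetime, datetime, str]] = []
    for bout in bouts:
        if bout.posture not in LYING_POSTURES:
            continue
        for ep in episodes:
            lo = max(bout.start, ep.start, w0)
            hi = min(bout.end, ep.end, w1)
            if hi > lo:
                intervals.append((lo, hi, bout.posture))
    intervals.sort()
    total = left = right = 0.0
    for lo, hi, posture in intervals:
        minutes = (hi - lo).total_seconds() / 60.0
        total += minutes
        if posture == LYING_LEFT:
            left += minutes
        elif posture == LYING_RIGHT:
            right += minutes
    n_episodes = 0
    prev_end: datetime | None = None
    for lo, hi, _ in intervals:
        gap = (lo - prev_end).total_seconds() / 60.0 if prev_end else None
        if prev_end is None or gap >= episode_gap_min:
            n_episodes += 1
        prev_end = max(prev_end, hi) if prev_end else hi
    return RecumbencyNightStats(
        night=night, recumbent_sleep_min=total, n_episodes=n_episodes,
        left_min=left, right_min=right,
    )


def recumbency_gap_run(daily_rsd_min: Sequence[float]) -> int:
    """Longest run of consecutive days with zero recumbent sleep."""
    best = run = 0
    for v in daily_rsd_min:
        if v == 0:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best
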