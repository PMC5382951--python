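"""The statistical battery: OLS, allometric power law, paired t, event-time
statistics on the night timeline, summary statistics and a moon-phase
stratification of recumbent sleep.

p-values are reported uncorrected (single pre-planned comparisons).  All
standard deviations are sample (n − 1) deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .timebase_io import clock_to_night_minutes

__all__ = [
    "RegressionResult", "AllometricModel", "EventTimeStats",
    "ols", "powerlaw_fit", "powerlaw_predict", "paired_t",
    "event_relative_stats", "summary_battery", "moon_stratified_recumbency",
    "ALL_MAMMAL_MODEL", "HERBIVORE_MODEL",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_uncorrected: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, float) + self.intercept


@dataclass(frozen=True)
class AllometricModel:
    """TST = a · Mb^b with body mass in grams and TST in hours."""

    coefficient: float
    exponent: float


#: published across-mammal and herbivore-only scaling models (mass in g)
ALL_MAMMAL_MODEL = AllometricModel(coefficient=17.946, exponent=-0.076)
HERBIVORE_MODEL = AllometricModel(coefficient=21.995, exponent=-0.14)


@dataclass(frozen=True)
class EventTimeStats:
    mean_min: float
    sd_min: float
    min_min: float
    max_min: float
    n: int


def ols(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with r² and the slope's t-test p.

    Requires n ≥ 3 finite pairs and non-degenerate x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.var(x) == 0:
        raise ValueError("degenerate input: var(x) = 0")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2), p_uncorrected=float(fit.pvalue),
        n=len(x),
    )


def powerlaw_fit(masses_g: Sequence[float], tst_h: Sequence[float]) -> AllometricModel:
    """Fit TST = a · Mb^b by OLS of ln(TST) on ln(Mb)."""
    m = np.asarray(masses_g, float)
    t = np.asarray(tst_h, float)
    if np.any(m <= 0) or np.any(t <= 0):
        raise ValueError("power-law fit needs strictly positive inputs")
    fit = ols(np.log(m), np.log(t))
    return AllometricModel(coefficient=float(np.exp(fit.intercept)),
                           exponent=fit.slope)


def powerlaw_predict(model: AllometricModel, mass_g: float) -> float:
    """Predicted total sleep time in hours at body mass ``mass_g`` grams."""
    if mass_g <= 0:
        raise ValueError("body mass must be positive")
    return model.coefficient * mass_g ** model.exponent


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on x − y; returns (t, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.allclose(d, d[0]):
        if np.all(d == 0):
            return 0.0, 1.0
        raise ValueError("degenerate input: zero-variance differences")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def event_relative_stats(event_times: Sequence[time | str | None],
                         reference_times: Sequence[time | str | None]
                         ) -> EventTimeStats:
    """Statistics of signed minutes from reference to event on the night timeline.

    Both sequences hold clock times; each is mapped to minutes since the
    12:00 start of the night window, so an evening reference (e.g. sunset)
    and a post-midnight event difference correctly across midnight.  Nights
    where either time is missing are skipped.
    """
    diffs = []
    for ev, ref in zip(event_times, reference_times, strict=True):
        if ev is None or ref is None or (isinstance(ev, float) and np.isnan(ev)) \
                or (isinstance(ref, float) and np.isnan(ref)):
            continue
        diffs.append(clock_to_night_minutes(ev) - clock_to_night_minutes(ref))
    if not diffs:
        raise ValueError("no paired nights")
    arr = np.asarray(diffs, float)
    return EventTimeStats(
        mean_min=float(arr.mean()),
        sd_min=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        min_min=float(arr.min()), max_min=float(arr.max()), n=len(arr),
    )


def summary_battery(values: Sequence[float]) -> dict[str, float]:
    """mean, sample sd, min, max of finite values."""
    arr = np.asarray(values, float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("empty input")
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def moon_stratified_recumbency(daily_rsd_min: Sequence[float],
                               moon_illum_pct: Sequence[float],
                               illum_thresh_pct: float = 50.0) -> float:
    """Fraction of recumbent-sleep minutes on nights with dim moon.

    Sums recumbent minutes over nights whose moon illumination is below
    ``illum_thresh_pct`` and divides by the total recumbent minutes.
    """
    rsd = np.asarray(daily_rsd_min, float)
    mi = np.asarray(moon_illum_pct, float)
    if rsd.shape != mi.shape:
        raise ValueError("aligned daily series required")
    ok = np.isfinite(rsd) & np.isfinite(mi)
    rsd, mi = rsd[ok], mi[ok]
    total = rsd.sum()
    if total == 0:
        raise ValueError("no recumbent sleep recorded")
    return float(rsd[mi < illum_thresh_pct].sum() / total)
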