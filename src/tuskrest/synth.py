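"""Coupled synthetic bio-logging streams with known ground truth.

The generator emits the five input streams of the pipeline — 1-min trunk
actigraphy, 1-min collar tri-axial acceleration, 1-min GPS fixes, 10-min
weather and a per-day astronomical table — for a configurable number of
noon-to-noon nights, together with the planted truth (episodes, onset,
offset, recumbent bouts, no-sleep nights, flight bouts, sleep sites).

Defaults emulate the statistical structure of wild-elephant sleep:
roughly two hours of polyphasic nocturnal sleep clustered towards the
pre-dawn hours, recumbency every third or fourth night in a single
30–70 min bout, rare (~7 %) no-sleep nights with a sustained ~30 km
displacement, and a diurnal weather cycle whose WBGT minimum falls
shortly before sunrise.  Sleep minutes carry zero activity counts; wake
minutes draw from an overdispersed positive count law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from . import environment
from .sleep_scoring import CONSOLIDATED_MIN
from .timebase_io import AnalysisNight, nights_for_range

__all__ = ["GeneratorConfig", "NightTruth", "SyntheticDataset", "generate",
           "recovery_report"]

MIN_PER_DAY = 1440


@dataclass
class GeneratorConfig:
    n_nights: int = 35
    first_morning: date = date(2014, 4, 14)
    # nightly total sleep, minutes (truncated normal, >= one block)
    tst_mean_min: float = 120.0
    tst_sd_min: float = 60.0
    # episodes per night
    episodes_mean: float = 5.0
    episodes_sd: float = 2.0
    main_fraction: float = 0.5
    # sleep placement density on the night timeline (clock 02:30 peak)
    sleep_peak_clock: time = time(2, 30)
    sleep_peak_sd_min: float = 100.0
    # recumbency: one bout every 3rd-4th sleeping night
    recumbency_min_period: int = 3
    recumbency_max_period: int = 4
    recumbency_bout_min: float = 30.0
    recumbency_bout_max: float = 70.0
    # nights without sleep
    p_no_sleep: float = 0.07
    flight_duration_min: float = 600.0
    flight_speed_kmh: float = 3.0
    # movement while awake
    wander_speed_kmh: float = 0.6
    start_lat: float = -18.10
    start_lon: float = 25.06
    # wake counts: 1 + NegBin(n, p)
    count_nb_n: float = 2.0
    count_nb_p: float = 0.01
    # weather diurnal cycle
    air_mean_c: float = 20.0
    air_amp_c: float = 8.0
    air_trough_clock: time = time(5, 40)
    rh_mean_pct: float = 60.0
    rh_amp_pct: float = 25.0
    # astro (printed-style, not ephemeris): drift per night in seconds
    sunset_start: time = time(18, 11)
    sunset_drift_s: float = -31.0
    sunrise_start: time = time(6, 32)
    sunrise_drift_s: float = 17.0
    seed: int | None = None


@dataclass
class NightTruth:
    night: AnalysisNight
    no_sleep: bool
    episodes: list[tuple[datetime, datetime]] = field(default_factory=list)
    onset: datetime | None = None
    offset: datetime | None = None
    recumbent_bouts: list[tuple[datetime, datetime, str]] = field(default_factory=list)
    flight: tuple[datetime, datetime] | None = None
    main_site: tuple[float, float] | None = None
    wbgt_min_time: datetime | None = None

    @property
    def tst_min(self) -> float:
        return sum((e - s).total_seconds() / 60.0 for s, e in self.episodes)

    @property
    def rsd_min(self) -> float:
        return sum((e - s).total_seconds() / 60.0 for s, e, _ in self.recumbent_bouts)


@dataclass
class SyntheticDataset:
    actigraphy: pd.DataFrame
    accel: pd.DataFrame
    gps: pd.DataFrame
    weather: pd.DataFrame
    astro: pd.DataFrame
    truth: list[NightTruth]
    config: GeneratorConfig


def _clock_min(t: time) -> int:
    return t.hour * 60 + t.minute


def _round5(x: float) -> int:
    return int(5 * round(x / 5.0))


def _plan_night(cfg: GeneratorConfig, rng: np.random.Generator,
                sunset_min: int, sunrise_min: int) -> list[tuple[int, int]]:
    """Plan episode (start, end) minutes on the night timeline (0 = 12:00).

    Episodes are 5-min aligned, non-overlapping, separated by >= 10 min,
    and confined between one hour after sunset and 10 min before sunrise,
    with starts drawn from a clock-time density peaking before dawn.  The
    main (first-planned, longest) episode is always consolidated.
    """
    tst = max(5.0, rng.normal(cfg.tst_mean_min, cfg.tst_sd_min))
    tst = max(5, _round5(tst))
    k = max(1, int(round(rng.normal(cfg.episodes_mean, cfg.episodes_sd))))
    k = min(k, tst // 5)
    main = max(CONSOLIDATED_MIN, _round5(cfg.main_fraction * tst))
    main = min(main, tst - 5 * (k - 1))
    main = max(main, CONSOLIDATED_MIN)
    rest_units = max(0, (tst - main) // 5)
    parts = min(k - 1, rest_units)
    if parts > 0:
        split = rng.multinomial(rest_units - parts, np.full(parts, 1.0 / parts)) + 1
        durations = [main] + [int(5 * u) for u in split]
    else:
        durations = [main]

    lo = _round5(sunset_min + 60)
    hi = _round5(sunrise_min - 10)
    peak = _clock_min(cfg.sleep_peak_clock) + 720  # clock 02:30 on night timeline
    placed: list[tuple[int, int]] = []

    def fits(s: int, d: int) -> bool:
        if s < lo or s + d > hi:
            return False
        return all(s + d + 10 <= ps or ps + pd_ + 10 <= s for ps, pd_ in placed)

    for d in durations:
        start = None
        for _ in range(200):
            cand = _round5(rng.normal(peak, cfg.sleep_peak_sd_min))
            if fits(cand, d):
                start = cand
                break
        if start is None:  # fall back to a deterministic scan
            for cand in range(lo, hi - d + 5, 5):
                if fits(cand, d):
                    start = cand
                    break
        if start is not None:
            placed.append((start, d))
    placed.sort()
    return [(s, s + d) for s, d in placed]


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate all five streams plus ground truth.  ``config.seed`` is required."""
    if config.seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nights = nights_for_range(cfg.first_morning, cfg.n_nights)
    origin = nights[0].window_start
    total_min = cfg.n_nights * MIN_PER_DAY
    times = pd.date_range(origin, periods=total_min, freq="1min")

    # ---- astro table -------------------------------------------------
    astro_rows = []
    sunsets: dict[date, int] = {}
    sunrises: dict[date, int] = {}
    for i in range(cfg.n_nights + 1):
        day = cfg.first_morning + timedelta(days=i - 1)
        ss = _clock_min(cfg.sunset_start) + round(i * cfg.sunset_drift_s / 60.0)
        sr = _clock_min(cfg.sunrise_start) + round(i * cfg.sunrise_drift_s / 60.0)
        sunsets[day], sunrises[day] = ss, sr
        moon_phase = (i % 30) / 30.0
        moonrise = (16 * 60 + 50 + i * 50) % MIN_PER_DAY
        moonset = (5 * 60 + 30 + i * 50) % MIN_PER_DAY
        astro_rows.append({
            "date": day.isoformat(),
            "sunset": f"{ss // 60}:{ss % 60:02d}",
            "sunrise": f"{sr // 60}:{sr % 60:02d}",
            "civil_off_min": 22.0, "nautical_off_min": 47.0, "astro_off_min": 73.0,
            "moonrise": f"{moonrise // 60}:{moonrise % 60:02d}",
            "moonset": f"{moonset // 60}:{moonset % 60:02d}",
            "moon_illum_pct": round(50.0 * (1 + np.cos(2 * np.pi * moon_phase)), 1),
        })
    astro = pd.DataFrame(astro_rows)

    # ---- night plans -------------------------------------------------
    sleep_mask = np.zeros(total_min, dtype=bool)
    lying = np.zeros(total_min, dtype=np.int8)  # 0 none, -1 left, +1 right
    flight_mask = np.zeros(total_min, dtype=bool)
    truths: list[NightTruth] = []
    next_recumbent = int(rng.integers(cfg.recumbency_min_period,
                                      cfg.recumbency_max_period + 1)) - 1
    sleeping_nights_seen = 0
    for ni, night in enumerate(nights):
        base = ni * MIN_PER_DAY
        evening = night.label_date - timedelta(days=1)
        sunset_nm = sunsets[evening] - 720          # night-timeline minutes
        sunrise_nm = sunrises[night.label_date] + 720
        no_sleep = bool(rng.random() < cfg.p_no_sleep)
        truth = NightTruth(night=night, no_sleep=no_sleep)
        if no_sleep:
            f0 = base + sunset_nm + int(rng.integers(30, 120))
            f1 = min(f0 + int(cfg.flight_duration_min), base + MIN_PER_DAY)
            flight_mask[f0:f1] = True
            truth.flight = (origin + timedelta(minutes=f0),
                            origin + timedelta(minutes=f1))
        else:
            plan = _plan_night(cfg, rng, sunset_nm, sunrise_nm)
            for s, e in plan:
                sleep_mask[base + s:base + e] = True
                truth.episodes.append((origin + timedelta(minutes=base + s),
                                       origin + timedelta(minutes=base + e)))
            # ground-truth consolidated onset / offset by the same definition
            sunset_abs = origin + timedelta(minutes=base + sunset_nm)
            sunrise_abs = origin + timedelta(minutes=base + sunrise_nm)
            consolidated = [(s, e) for s, e in truth.episodes
                            if (e - s).total_seconds() / 60.0 >= CONSOLIDATED_MIN]
            after_sunset = [s for s, _ in consolidated if s >= sunset_abs]
            before_sunrise = [e for _, e in consolidated if e <= sunrise_abs]
            truth.onset = min(after_sunset) if after_sunset else None
            truth.offset = max(before_sunrise) if before_sunrise else None

            sleeping_nights_seen += 1
            if sleeping_nights_seen > next_recumbent and plan:
                main_s, main_e = max(plan, key=lambda p: p[1] - p[0])
                main_dur = main_e - main_s
                bout = _round5(min(main_dur,
                                   rng.uniform(cfg.recumbency_bout_min,
                                               cfg.recumbency_bout_max)))
                bout = max(5, min(bout, main_dur))
                b0 = main_s + _round5(rng.uniform(0, main_dur - bout))
                side = "left" if rng.random() < 0.5 else "right"
                lying[base + b0:base + b0 + bout] = -1 if side == "left" else 1
                truth.recumbent_bouts.append(
                    (origin + timedelta(minutes=base + b0),
                     origin + timedelta(minutes=base + b0 + bout), side))
                sleeping_nights_seen = 0
                next_recumbent = int(rng.integers(cfg.recumbency_min_period,
                                                  cfg.recumbency_max_period + 1)) - 1
        truths.append(truth)

    # ---- actigraphy --------------------------------------------------
    counts = 1 + rng.negative_binomial(cfg.count_nb_n, cfg.count_nb_p, total_min)
    counts[sleep_mask] = 0
    actigraphy = pd.DataFrame({"timestamp": times, "count": counts.astype(int)})

    # ---- accelerometer ----------------------------------------------
    quiescent = sleep_mask | (lying != 0)
    mag = np.where(quiescent, 1.0 + rng.normal(0, 0.02, total_min),
                   1.0 + rng.normal(0, 0.12, total_min))
    ux = np.where(lying != 0, 0.97 * np.sign(lying), rng.normal(0, 0.05, total_min))
    uy = rng.normal(0, 0.05, total_min)
    uz = np.where(lying != 0, -0.20, 0.98 + rng.normal(0, 0.02, total_min))
    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
    ax, ay, az = (mag * ux / norm, mag * uy / norm, mag * uz / norm)
    accel = pd.DataFrame({"timestamp": times,
                          "ax_g": np.round(ax, 4), "ay_g": np.round(ay, 4),
                          "az_g": np.round(az, 4)})

    # ---- GPS ---------------------------------------------------------
    speed = np.abs(rng.normal(cfg.wander_speed_kmh, cfg.wander_speed_kmh / 2,
                              total_min))
    speed[flight_mask] = rng.normal(cfg.flight_speed_kmh, 0.2, int(flight_mask.sum()))
    speed[sleep_mask | (lying != 0)] = 0.0
    heading = np.cumsum(rng.normal(0, 0.4, total_min))
    # flights hold a fixed heading to build up displacement
    if flight_mask.any():
        idx = np.flatnonzero(flight_mask)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            heading[run] = heading[run[0]]
    step_km = speed / 60.0
    dlat = step_km * np.cos(heading) / 111.2
    dlon = step_km * np.sin(heading) / (111.32 * np.cos(np.radians(cfg.start_lat)))
    lat = cfg.start_lat + np.concatenate([[0.0], np.cumsum(dlat)[:-1]])
    lon = cfg.start_lon + np.concatenate([[0.0], np.cumsum(dlon)[:-1]])
    gps = pd.DataFrame({"timestamp": times, "lat": np.round(lat, 6),
                        "lon": np.round(lon, 6)})
    for truth in truths:
        if truth.episodes:
            main_s, _ = max(truth.episodes, key=lambda p: p[1] - p[0])
            i = int((main_s - origin).total_seconds() // 60)
            truth.main_site = (float(lat[i]), float(lon[i]))

    # ---- weather (10-min cadence) ------------------------------------
    wt = pd.date_range(origin, periods=total_min // 10, freq="10min")
    clock = (wt.hour * 60 + wt.minute).to_numpy(float)
    trough = _clock_min(cfg.air_trough_clock)
    phase = 2 * np.pi * (clock - trough) / MIN_PER_DAY
    air = cfg.air_mean_c - cfg.air_amp_c * np.cos(phase) + rng.normal(0, 0.2, len(wt))
    rh = np.clip(cfg.rh_mean_pct + cfg.rh_amp_pct * np.cos(phase)
                 + rng.normal(0, 1.0, len(wt)), 6.0, 99.0)
    day_frac = np.clip(np.sin(np.pi * (clock - 6.5 * 60) / (11.0 * 60)), 0.0, None)
    solar = 900.0 * day_frac + rng.normal(0, 5.0, len(wt)).clip(0)
    globe = air + 10.0 * day_frac
    weather = pd.DataFrame({
        "timestamp": wt,
        "air_c": np.round(air, 2), "globe_c": np.round(globe, 2),
        "rh_pct": np.round(rh, 2),
        "wind_kmh": np.round(np.abs(rng.normal(3, 2, len(wt))), 2),
        "wind_deg": np.round(rng.uniform(0, 360, len(wt)), 1),
        "rain_mm": np.zeros(len(wt)),
        "illum_klx": np.round(130.0 * day_frac, 2),
        "solar_wm2": np.round(solar, 2),
    })

    # truth WBGT minimum time from the emitted series (consistent by construction)
    env = environment.wbgt_series(weather)
    for truth in truths:
        truth.wbgt_min_time = environment.daily_min(env, truth.night).time_of_min

    return SyntheticDataset(actigraphy=actigraphy, accel=accel, gps=gps,
                            weather=weather, astro=astro, truth=truths,
                            config=cfg)


def recovery_report(truth: Sequence[NightTruth], nights_df: pd.DataFrame) -> pd.DataFrame:
    """Absolute per-night errors of pipeline outputs against planted truth.

    ``nights_df`` is the per-night summary table produced by the pipeline
    (one row per night, indexed by ``date``).  Reported error columns:
    ``tst_err_min``, ``onset_err_min``, ``offset_err_min``, ``rsd_err_min``.
    Raises when the night sets disagree.
    """
    by_date = {pd.Timestamp(d).date(): row
               for d, row in nights_df.set_index("date").iterrows()}
    truth_dates = {t.night.label_date for t in truth}
    if truth_dates != set(by_date):
        raise ValueError("mismatched night sets between truth and pipeline output")
    rows = []
    for t in truth:
        row = by_date[t.night.label_date]

        def _tdiff(a, b):
            if a is None and (b is None or pd.isna(b)):
                return 0.0
            if a is None or b is None or pd.isna(b):
                return np.nan
            return abs((pd.Timestamp(b) - pd.Timestamp(a)).total_seconds()) / 60.0

        rows.append({
            "date": t.night.label_date,
            "tst_err_min": abs(t.tst_min - float(row["tst_h"]) * 60.0),
            "onset_err_min": _tdiff(t.onset, row.get("onset")),
            "offset_err_min": _tdiff(t.offset, row.get("offset")),
            "rsd_err_min": abs(t.rsd_min - float(row["rsd_min"])),
        })
    return pd.DataFrame(rows)
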