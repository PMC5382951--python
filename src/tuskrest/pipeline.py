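"""End-to-end orchestration and the printed-table statistics report.

``run_streams`` drives every stage — epoch scoring, modal aggregation,
episode detection, posture intersection, WBGT context and sleep-site
geometry — over in-memory streams and returns the per-night summary
table.  ``run_all`` is the file-based wrapper used by the CLI.
``reproduce_paper`` recomputes the published per-night summary statistics
from the packaged printed tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import environment, movement, posture, sleep_scoring, stats
from .timebase_io import (AnalysisNight, AstroDay, astro_from_frame,
                          clock_to_night_minutes, load_astro, load_table2,
                          load_table3, read_series)

__all__ = ["RunConfig", "run_streams", "run_all", "reproduce_paper"]


@dataclass
class RunConfig:
    actigraphy: Path
    accel: Path | None
    gps: Path | None
    weather: Path | None
    astro: Path
    outdir: Path
    animal: str = "A1"
    active_threshold: int = 0
    block_min: int = sleep_scoring.BLOCK_MIN
    speed_thresh_kmh: float = 1.5
    bout_min_duration_min: float = 120.0
    moving_avg_min: int = 15
    earth_radius_km: float = movement.EARTH_RADIUS_KM
    extra: dict = field(default_factory=dict)


def _nights_covering(index: pd.DatetimeIndex) -> list[AnalysisNight]:
    first = index[0]
    # the first analysis night is the one whose window contains the first sample
    start = AnalysisNight(first.date() + timedelta(days=1)
                          if first.time() >= pd.Timestamp("12:00").time()
                          else first.date())
    nights = []
    night = start
    while night.window_start <= index[-1]:
        nights.append(night)
        night = AnalysisNight(night.label_date + timedelta(days=1))
    return nights


def run_streams(actigraphy: pd.DataFrame,
                astro: Mapping[date, AstroDay] | pd.DataFrame,
                accel: pd.DataFrame | None = None,
                gps: pd.DataFrame | None = None,
                weather: pd.DataFrame | None = None,
                nights: Sequence[AnalysisNight] | None = None,
                active_threshold: int = 0,
                block_min: int = sleep_scoring.BLOCK_MIN) -> pd.DataFrame:
    """Run every applicable stage and return one summary row per night."""
    if isinstance(astro, pd.DataFrame):
        astro = astro_from_frame(astro)
    active = sleep_scoring.score_epochs(actigraphy, active_threshold)
    blocks = sleep_scoring.aggregate_modal(active, block_min)
    if nights is None:
        nights = _nights_covering(active.index)

    bouts = None
    if accel is not None:
        postures = posture.classify_samples(accel)
        bouts = posture.posture_bouts(postures)
    env = environment.wbgt_series(weather) if weather is not None else None

    rows = []
    prev_main: tuple | None = None  # (start datetime, lat, lon)
    for night in nights:
        episodes = sleep_scoring.detect_episodes(blocks, night, block_min)
        summary = sleep_scoring.night_summary(episodes, astro, night, blocks)
        row = {
            "date": night.label_date,
            "tst_h": summary.tst_h,
            "n_episodes": summary.n_episodes,
            "mse_h": summary.main_episode_h,
            "onset": summary.onset,
            "offset": summary.offset,
            "no_sleep": summary.no_sleep,
            "nocturnal_fraction": summary.nocturnal_fraction,
            "rsd_min": np.nan, "rsd_left_min": np.nan, "rsd_right_min": np.nan,
            "n_recumbent_episodes": np.nan,
            "wbgt_min_c": np.nan, "wbgt_min_time": pd.NaT,
            "wbgt_onset_c": np.nan, "wbgt_offset_c": np.nan,
            "site_lat": np.nan, "site_lon": np.nan,
            "sld_km": np.nan, "path_km": np.nan,
        }
        if bouts is not None:
            rec = posture.recumbent_sleep(bouts, episodes, night)
            row.update(rsd_min=rec.recumbent_sleep_min,
                       rsd_left_min=rec.left_min, rsd_right_min=rec.right_min,
                       n_recumbent_episodes=rec.n_episodes)
        if env is not None:
            dm = environment.daily_min(env, night)
            row.update(wbgt_min_c=dm.wbgt_min_c, wbgt_min_time=dm.time_of_min)
            if summary.onset is not None:
                row["wbgt_onset_c"] = environment.wbgt_at(env, summary.onset)
            if summary.offset is not None:
                row["wbgt_offset_c"] = environment.wbgt_at(env, summary.offset)
        if gps is not None and not summary.no_sleep and episodes:
            main = max(episodes, key=lambda e: e.duration_min)
            ts = pd.to_datetime(gps["timestamp"])
            i = ts.searchsorted(main.start, side="right") - 1
            if i >= 0:
                lat, lon = float(gps["lat"].iloc[i]), float(gps["lon"].iloc[i])
                row.update(site_lat=lat, site_lon=lon)
                if prev_main is not None:
                    seg = movement.path_and_straightline(gps, prev_main[0], main.start)
                    row.update(sld_km=movement.haversine(prev_main[1], prev_main[2],
                                                         lat, lon),
                               path_km=seg.path_km)
                prev_main = (main.start, lat, lon)
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """File-based pipeline run: write ``nights.csv`` and ``report.json``.

    Returns the nights table and the statistics report.  The report also
    records the full effective parameter set for provenance.
    """
    actigraphy = read_series(config.actigraphy, "actigraphy")
    astro = load_astro(config.astro)
    accel = read_series(config.accel, "accel") if config.accel else None
    gps = read_series(config.gps, "gps") if config.gps else None
    weather = read_series(config.weather, "weather") if config.weather else None

    nights_df = run_streams(actigraphy, astro, accel=accel, gps=gps,
                            weather=weather,
                            active_threshold=config.active_threshold,
                            block_min=config.block_min)
    report = _report_from_nights(nights_df)
    report["parameters"] = {
        "animal": config.animal,
        "active_threshold": config.active_threshold,
        "block_min": config.block_min,
        "speed_thresh_kmh": config.speed_thresh_kmh,
        "bout_min_duration_min": config.bout_min_duration_min,
        "moving_avg_min": config.moving_avg_min,
        "earth_radius_km": config.earth_radius_km,
    }
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nights_df.to_csv(outdir / "nights.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return nights_df, report


def _report_from_nights(nights: pd.DataFrame) -> dict:
    """Summary statistics over one animal's nights table."""
    slept = nights[~nights["no_sleep"]]
    report = {
        "n_nights": int(len(nights)),
        "n_no_sleep": int(nights["no_sleep"].sum()),
        "tst_h": stats.summary_battery(nights["tst_h"].fillna(0.0)),
        "tst_h_sleeping_nights": stats.summary_battery(slept["tst_h"])
        if len(slept) else None,
        "mse_h": stats.summary_battery(slept["mse_h"]) if len(slept) else None,
    }
    if nights["rsd_min"].notna().any():
        rsd = nights["rsd_min"].fillna(0.0)
        report["rsd_total_min"] = float(rsd.sum())
        report["rsd_min"] = stats.summary_battery(rsd)
        report["max_days_without_recumbency"] = posture.recumbency_gap_run(rsd)
    if nights["sld_km"].notna().any():
        report["sld_km"] = stats.summary_battery(nights["sld_km"].dropna())
        report["path_km"] = stats.summary_battery(nights["path_km"].dropna())
    ok = nights.dropna(subset=["wbgt_min_c", "wbgt_onset_c"])
    if len(ok) >= 3:
        fit = stats.ols(ok["wbgt_min_c"], ok["wbgt_onset_c"])
        report["wbgt_onset_on_min"] = {
            "slope": fit.slope, "intercept": fit.intercept,
            "r2": fit.r_squared, "p_uncorrected": fit.p_uncorrected, "n": fit.n,
        }
    ok = nights.dropna(subset=["wbgt_min_c", "wbgt_offset_c"])
    if len(ok) >= 3:
        fit = stats.ols(ok["wbgt_min_c"], ok["wbgt_offset_c"])
        report["wbgt_offset_on_min"] = {
            "slope": fit.slope, "intercept": fit.intercept,
            "r2": fit.r_squared, "p_uncorrected": fit.p_uncorrected, "n": fit.n,
        }
    return report


# ---------------------------------------------------------------------------
# Printed-table reproduction
# ---------------------------------------------------------------------------

def _clock_or_none(v):
    return None if (v is None or (isinstance(v, float) and np.isnan(v))) else v


def reproduce_paper() -> dict:
    """Recompute the published summary statistics from the packaged tables.

    Every value is computed at call time from the per-night data; nothing
    is read back from the published prose.
    """
    t2 = load_table2()
    t3 = load_table3()
    out: dict = {}

    both_tst = t2["tst_h"]
    out["tst_mean_h_combined_incl_no_sleep"] = float(both_tst.fillna(0.0).mean())
    out["tst_sd_h_combined_incl_no_sleep"] = float(both_tst.fillna(0.0).std(ddof=1))
    out["tst_mean_h_combined_excl_no_sleep"] = float(both_tst.dropna().mean())

    for animal in ("M1", "M2"):
        sub = t2[t2["animal"] == animal]
        tst = sub["tst_h"]
        key = animal.lower()
        out[f"tst_mean_h_{key}_incl_no_sleep"] = float(tst.fillna(0.0).mean())
        out[f"tst_mean_h_{key}_excl_no_sleep"] = float(tst.dropna().mean())
        out[f"tst_sd_h_{key}_excl_no_sleep"] = float(tst.dropna().std(ddof=1))
        out[f"rsd_total_min_{key}"] = float(sub["rsd_min"].sum())
        out[f"max_days_without_recumbency_{key}"] = posture.recumbency_gap_run(
            sub["rsd_min"].to_list())

        onset_stats = stats.event_relative_stats(
            [_clock_or_none(v) for v in sub["onset"]],
            [_clock_or_none(v) for v in sub["sunset"]])
        out[f"onset_after_sunset_min_{key}"] = {
            "mean": onset_stats.mean_min, "sd": onset_stats.sd_min,
            "min": onset_stats.min_min, "max": onset_stats.max_min,
            "n": onset_stats.n,
        }
        offset_stats = stats.event_relative_stats(
            [_clock_or_none(v) for v in sub["offset"]],
            [_clock_or_none(v) for v in sub["sunrise"]])
        out[f"offset_before_sunrise_min_{key}"] = {
            "mean": -offset_stats.mean_min, "sd": offset_stats.sd_min,
            "min": -offset_stats.max_min, "max": -offset_stats.min_min,
            "n": offset_stats.n,
        }

        fit = stats.ols(sub["wbgt_min_c"], sub["wbgt_onset_c"])
        out[f"wbgt_onset_on_min_{key}"] = {
            "slope": fit.slope, "intercept": fit.intercept,
            "r2": fit.r_squared, "p_uncorrected": fit.p_uncorrected, "n": fit.n,
        }
        fit = stats.ols(sub["wbgt_min_c"], sub["wbgt_offset_c"])
        out[f"wbgt_offset_on_min_{key}"] = {
            "slope": fit.slope, "intercept": fit.intercept,
            "r2": fit.r_squared, "p_uncorrected": fit.p_uncorrected, "n": fit.n,
        }
        out[f"wbgt_onset_excess_mean_c_{key}"] = float(
            (sub["wbgt_onset_c"] - sub["wbgt_min_c"]).dropna().mean())
        out[f"wbgt_offset_excess_mean_c_{key}"] = float(
            (sub["wbgt_offset_c"] - sub["wbgt_min_c"]).dropna().mean())

        # paired test: onset time vs time of minimum WBGT, night-timeline minutes
        paired = sub.dropna(subset=["onset", "wbgt_min_time"])
        t_stat, p = stats.paired_t(
            [clock_to_night_minutes(v) for v in paired["onset"]],
            [clock_to_night_minutes(v) for v in paired["wbgt_min_time"]])
        out[f"onset_vs_wbgt_min_time_paired_t_{key}"] = {"t": t_stat, "p": p}

        out[f"sld_mean_km_{key}"] = float(sub["sld_km"].dropna().mean())
        out[f"path_mean_km_{key}"] = float(sub["path_km"].dropna().mean())
        out[f"tac_mean_{key}"] = float(sub["tac"].dropna().mean())

        sites = t3[t3["animal"] == animal][["date", "lat", "lon"]]
        cons = movement.consecutive_site_distances(sites)
        merged = sub.merge(cons, on="date", how="left")
        printed = merged["sld_km"]
        computed = merged["distance_km"]
        overlap = printed.notna() & computed.notna()
        out[f"sld_route_max_abs_diff_km_{key}"] = float(
            (printed[overlap] - computed[overlap]).abs().max())
        # the first printed distance has no predecessor site in the
        # coordinate table; it enters as printed input
        combined = computed.where(computed.notna(), printed)
        out[f"sld_mean_km_from_sites_{key}"] = float(combined.dropna().mean())

    out["n_no_sleep_nights_total"] = int(t2["no_sleep"].sum())

    # same-night inter-animal distance from the printed per-day column
    out["inter_animal_sld_mean_km"] = float(
        t2.drop_duplicates("date")["dist_m1_m2_km"].dropna().mean())

    # moon stratification of recumbent sleep, both animals combined
    daily = t2.pivot_table(index="date", values="rsd_min", aggfunc="sum")
    moon = t2.drop_duplicates("date").set_index("date")["moon_illum_pct"]
    out["recumbency_fraction_moon_below_50pct"] = stats.moon_stratified_recumbency(
        daily["rsd_min"].reindex(moon.index).to_numpy(),
        moon.to_numpy())

    # allometric predictions from the published scaling models (mass in kg here)
    out["allometric_pred_h_all_mammal_6300kg"] = stats.powerlaw_predict(
        stats.ALL_MAMMAL_MODEL, 6300e3)
    out["allometric_pred_h_all_mammal_2400kg"] = stats.powerlaw_predict(
        stats.ALL_MAMMAL_MODEL, 2400e3)
    out["allometric_pred_h_herbivore_2400kg"] = stats.powerlaw_predict(
        stats.HERBIVORE_MODEL, 2400e3)
    out["allometric_pred_h_herbivore_6300kg"] = stats.powerlaw_predict(
        stats.HERBIVORE_MODEL, 6300e3)
    return out
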