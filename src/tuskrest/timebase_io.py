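"""Time conventions, typed CSV schemas and packaged-table loaders.

All timestamps are naive local civil time (the study site uses a single
fixed UTC+2 offset with no daylight-saving transitions, so naive datetimes
are unambiguous).  The *analysis night* runs from 12:00 on one calendar day
to 12:00 on the next and is labelled by the morning date, so that an
evening sleep onset and the following pre-dawn offset fall in the same
night.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "OrderingError",
    "FixtureError",
    "SCHEMAS",
    "AnalysisNight",
    "AstroDay",
    "read_series",
    "write_series",
    "parse_ddmm_coordinate",
    "parse_clock",
    "clock_to_night_minutes",
    "nights_for_range",
    "load_table2",
    "load_table3",
    "load_astro",
    "astro_from_frame",
]


class SchemaError(ValueError):
    """A CSV does not match the named schema (missing column, bad value)."""


class OrderingError(ValueError):
    """Timestamps are not strictly increasing at the required cadence."""


class FixtureError(RuntimeError):
    """A packaged data table failed its integrity check."""


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

#: name -> (columns, cadence seconds or None, row validator)
SCHEMAS: dict[str, dict] = {
    "actigraphy": {
        "columns": ["timestamp", "count"],
        "cadence_s": 60,
        "dtypes": {"count": int},
    },
    "accel": {
        "columns": ["timestamp", "ax_g", "ay_g", "az_g"],
        "cadence_s": 60,
        "dtypes": {"ax_g": float, "ay_g": float, "az_g": float},
    },
    "gps": {
        "columns": ["timestamp", "lat", "lon"],
        "cadence_s": 60,
        "dtypes": {"lat": float, "lon": float},
    },
    "weather": {
        "columns": [
            "timestamp", "air_c", "globe_c", "rh_pct", "wind_kmh",
            "wind_deg", "rain_mm", "illum_klx", "solar_wm2",
        ],
        "cadence_s": 600,
        "dtypes": {c: float for c in (
            "air_c", "globe_c", "rh_pct", "wind_kmh", "wind_deg",
            "rain_mm", "illum_klx", "solar_wm2")},
    },
    "astro": {
        "columns": [
            "date", "sunset", "sunrise", "civil_off_min", "nautical_off_min",
            "astro_off_min", "moonrise", "moonset", "moon_illum_pct",
        ],
        "cadence_s": None,
        "dtypes": {
            "civil_off_min": float, "nautical_off_min": float,
            "astro_off_min": float, "moon_illum_pct": float,
        },
    },
}

#: per-schema value bounds checked on read and write
_BOUNDS = {
    "actigraphy": {"count": (0, None)},
    "accel": {"ax_g": (-4.0, 4.0), "ay_g": (-4.0, 4.0), "az_g": (-4.0, 4.0)},
    "gps": {"lat": (-90.0, 90.0), "lon": (-180.0, 180.0)},
    "weather": {"rh_pct": (0.0, 100.0)},
    "astro": {"moon_illum_pct": (0.0, 100.0)},
}


def _validate(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    spec = SCHEMAS[schema]
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"schema {schema!r}: missing columns {missing}")
    df = df[spec["columns"]].copy()
    for col, (lo, hi) in _BOUNDS.get(schema, {}).items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if lo is not None:
            bad |= vals < lo
        if hi is not None:
            bad |= vals > hi
        if bad.any():
            raise SchemaError(
                f"schema {schema!r}: {int(bad.sum())} value(s) of {col!r} "
                f"outside [{lo}, {hi}]"
            )
    if "timestamp" in df.columns:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        if not df["timestamp"].is_monotonic_increasing or df["timestamp"].duplicated().any():
            raise OrderingError(f"schema {schema!r}: timestamps not strictly increasing")
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.date
    for col, typ in spec.get("dtypes", {}).items():
        df[col] = df[col].astype(typ)
    return df


def read_series(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV stream against a named schema.

    Returns a time-sorted DataFrame with exactly the schema's columns and
    parsed timestamps.  Raises :class:`SchemaError` for missing columns or
    out-of-bound values and :class:`OrderingError` for non-monotone time.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; know {sorted(SCHEMAS)}")
    return _validate(pd.read_csv(path), schema)


def write_series(df: pd.DataFrame, path, schema: str) -> None:
    """Validate and write a stream so that ``read_series`` round-trips it."""
    out = _validate(df, schema)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Clock / night helpers
# ---------------------------------------------------------------------------

NOON = time(12, 0)


def parse_clock(value: str) -> time:
    """Parse a printed clock time like ``"19:00"`` or ``"6:32"``."""
    h, m = value.strip().split(":")
    return time(int(h), int(m))


@dataclass(frozen=True)
class AnalysisNight:
    """One noon-to-noon analysis night, labelled by the morning date."""

    label_date: date

    @property
    def window_start(self) -> datetime:
        return datetime.combine(self.label_date - timedelta(days=1), NOON)

    @property
    def window_end(self) -> datetime:
        return datetime.combine(self.label_date, NOON)

    def contains(self, t: datetime) -> bool:
        return self.window_start <= t < self.window_end

    def clock_datetime(self, clock: time | str) -> datetime:
        """Place a clock time on the night timeline.

        Times from 12:00 onward belong to the evening (label date − 1),
        times before 12:00 to the morning of the label date.
        """
        if isinstance(clock, str):
            clock = parse_clock(clock)
        day = self.label_date - timedelta(days=1) if clock >= NOON else self.label_date
        return datetime.combine(day, clock)


def clock_to_night_minutes(clock: time | str) -> float:
    """Minutes since the 12:00 start of the night window for a clock time."""
    if isinstance(clock, str):
        clock = parse_clock(clock)
    minutes = clock.hour * 60 + clock.minute + clock.second / 60.0
    return minutes - 720.0 if minutes >= 720.0 else minutes + 720.0


def nights_for_range(first_morning: date, n_nights: int) -> list[AnalysisNight]:
    """``n_nights`` consecutive analysis nights; windows tile with no gaps."""
    return [AnalysisNight(first_morning + timedelta(days=i)) for i in range(n_nights)]


@dataclass(frozen=True)
class AstroDay:
    """Per-day astronomical events (inputs, never computed here)."""

    date: date
    sunset: time
    sunrise: time
    civil_off_min: float
    nautical_off_min: float
    astro_off_min: float
    moonrise: time | None
    moonset: time | None
    moon_illum_pct: float


def load_astro(path) -> dict[date, AstroDay]:
    """Load an astro CSV into a per-date lookup."""
    return astro_from_frame(read_series(path, "astro"))


def astro_from_frame(df: pd.DataFrame) -> dict[date, AstroDay]:
    """Build the per-date astro lookup from a validated astro DataFrame."""
    df = _validate(df, "astro")
    out: dict[date, AstroDay] = {}
    for row in df.itertuples(index=False):
        out[row.date] = AstroDay(
            date=row.date,
            sunset=parse_clock(row.sunset),
            sunrise=parse_clock(row.sunrise),
            civil_off_min=float(row.civil_off_min),
            nautical_off_min=float(row.nautical_off_min),
            astro_off_min=float(row.astro_off_min),
            moonrise=parse_clock(row.moonrise) if isinstance(row.moonrise, str) else None,
            moonset=parse_clock(row.moonset) if isinstance(row.moonset, str) else None,
            moon_illum_pct=float(row.moon_illum_pct),
        )
    return out


# ---------------------------------------------------------------------------
# Coordinate parsing
# ---------------------------------------------------------------------------

def parse_ddmm_coordinate(value: float) -> float:
    """Convert a degrees + decimal-minutes number (DD.MMmmm) to decimal degrees.

    ``18.05649`` encodes 18° 5.649′ = 18 + 5.649/60 = 18.09415°.  The
    fractional part, read as minutes, must be below 60.

    >>> round(parse_ddmm_coordinate(18.30000), 4)
    18.5
    """
    if value < 0:
        raise ValueError("coordinate magnitudes only; apply hemisphere sign afterwards")
    degrees = int(value)
    minutes = round((value - degrees) * 100.0, 10)
    if minutes >= 60.0:
        raise ValueError(f"{value}: minutes field {minutes} >= 60")
    return degrees + minutes / 60.0


# ---------------------------------------------------------------------------
# Packaged tables (the per-day dataset printed in the source study)
# ---------------------------------------------------------------------------

_EXPECTED_SHA256 = {
    "table2.csv": "28fcc5b95f6a7e2028f474cb28b1fcd44559803890a380ce8e028e6e8d4bb9ed",
    "table3.csv": "2d29f813366f619f44edefccfbf9675566f03c366be339d7124c9050e7071db6",
}

ANIMALS = ("M1", "M2")

#: Table-2 columns that exist once per animal
_PER_ANIMAL = {
    "onset": "onset", "offset": "offset", "tst_h": "tst_h", "mse_h": "mse_h",
    "rsd_min": "rsd_min", "wbgt_onset_c": "wbgt_onset_c",
    "wbgt_offset_c": "wbgt_offset_c", "sld_km": "sld_km", "path_km": "path_km",
    "tac": "tac",
}


def _fixture_text(name: str) -> str:
    text = resources.files("tuskrest.data").joinpath(name).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    expected = _EXPECTED_SHA256[name]
    if expected is not None and digest != expected:
        raise FixtureError(f"{name}: checksum mismatch ({digest})")
    return text


def load_table2() -> pd.DataFrame:
    """Load the per-night summary table, one row per animal-night.

    Columns: ``rd, date, animal, sunset, sunrise, moonrise, moonset,
    moon_illum_pct, wbgt_min_c, wbgt_min_time`` plus the per-animal fields
    ``onset, offset, tst_h, mse_h, rsd_min, wbgt_onset_c, wbgt_offset_c,
    sld_km, path_km, dist_m1_m2_km, tac`` and a derived ``no_sleep`` flag.
    Cells printed as missing are NaN/None — never zero — except recumbent
    minutes, where explicit zeros are printed.
    """
    from io import StringIO

    wide = pd.read_csv(StringIO(_fixture_text("table2.csv")))
    shared = ["rd", "date", "sunset", "sunrise", "moonrise", "moonset",
              "moon_illum_pct", "wbgt_min_c", "wbgt_min_time", "dist_m1_m2_km"]
    frames = []
    for animal in ANIMALS:
        suffix = "_" + animal.lower()
        cols = {f"{base}{suffix}": out for base, out in _PER_ANIMAL.items()}
        part = wide[shared + list(cols)].rename(columns=cols)
        part.insert(2, "animal", animal)
        frames.append(part)
    df = pd.concat(frames, ignore_index=True)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["no_sleep"] = df["tst_h"].isna()
    df = df.sort_values(["animal", "rd"]).reset_index(drop=True)
    _check_table2(df)
    return df


def _check_table2(df: pd.DataFrame) -> None:
    for animal, n_missing in (("M1", 3), ("M2", 2)):
        sub = df[df["animal"] == animal]
        if len(sub) != 35:
            raise FixtureError(f"{animal}: expected 35 rows, found {len(sub)}")
        if int(sub["no_sleep"].sum()) != n_missing:
            raise FixtureError(
                f"{animal}: expected {n_missing} no-sleep nights, "
                f"found {int(sub['no_sleep'].sum())}"
            )


def load_table3() -> pd.DataFrame:
    """Load the main-sleep-site coordinates, one row per animal-night.

    The printed values use a degrees + decimal-minutes encoding; both the
    raw fields (``lat_ddmm``, ``lon_ddmm``) and parsed decimal degrees
    (``lat``, ``lon``; south negative, east positive) are returned.  Nights
    without sleep have no site and carry NaNs.
    """
    from io import StringIO

    wide = pd.read_csv(StringIO(_fixture_text("table3.csv")))
    frames = []
    for animal in ANIMALS:
        suffix = "_" + animal.lower()
        part = wide[["rd", "date", f"lat_s_ddmm{suffix}", f"lon_e_ddmm{suffix}"]].rename(
            columns={f"lat_s_ddmm{suffix}": "lat_ddmm", f"lon_e_ddmm{suffix}": "lon_ddmm"}
        )
        part.insert(2, "animal", animal)
        frames.append(part)
    df = pd.concat(frames, ignore_index=True)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["lat"] = [
        -parse_ddmm_coordinate(v) if np.isfinite(v) else np.nan for v in df["lat_ddmm"]
    ]
    df["lon"] = [
        parse_ddmm_coordinate(v) if np.isfinite(v) else np.nan for v in df["lon_ddmm"]
    ]
    for animal in ANIMALS:
        if len(df[df["animal"] == animal]) != 35:
            raise FixtureError(f"{animal}: expected 35 site rows")
    return df.sort_values(["animal", "rd"]).reset_index(drop=True)
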