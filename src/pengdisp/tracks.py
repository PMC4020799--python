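"""Argos track filtering and migratory statistics.

Service Argos grades each satellite fix with a location class — 0, 1, 2
and 3 corresponding to nominal accuracies of >1 km, <1 km, <350 m and
<150 m.  Transmitters ran a 4 h on / 20 h off duty cycle switched on at
01:00 GMT, so at most one cluster of fixes arrives per day; the single
most accurate fix of each duty cycle is kept as that day's "daily
position", and all migratory statistics are computed from those.

Per-bird migratory parameters: duration of transmission, maximum
great-circle distance to the natal colony, minimum distance covered (the
sum of distances between consecutive daily positions — a lower bound on
the true path length), and the mean, sd and maximum of the daily
distances.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, asdict
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "DUTY_CYCLE_START_HOUR",
    "LOCATION_CLASSES",
    "great_circle_km",
    "read_fixes",
    "select_daily_positions",
    "MigrationSummary",
    "migration_summary",
    "cohort_stats",
    "load_reference_cohort",
]

EARTH_RADIUS_KM = 6371.0
#: Transmitters switch on at 01:00 GMT; a duty cycle is the 24 h window
#: starting there, which also bins any fix received outside an on-window.
DUTY_CYCLE_START_HOUR = 1
LOCATION_CLASSES = (0, 1, 2, 3)

_FIX_COLUMNS = ["bird_id", "timestamp", "lon", "lat", "location_class"]


def great_circle_km(a, b) -> float:
    """Haversine distance in km between (lon, lat) points, R = 6371 km.

    Accepts scalars or broadcastable arrays of lon/lat pairs.
    """
    lon1, lat1 = np.asarray(a[0], float), np.asarray(a[1], float)
    lon2, lat2 = np.asarray(b[0], float), np.asarray(b[1], float)
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude outside [-90, 90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    return float(d) if d.ndim == 0 else d


def _normalize_lon(lon):
    """Wrap longitudes into (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    wrapped = -((-lon + 180.0) % 360.0 - 180.0)
    return np.where(wrapped == -180.0, 180.0, wrapped)


def read_fixes(path_or_buf) -> pd.DataFrame:
    """Read an Argos fix table (CSV: bird_id, timestamp, lon, lat, location_class).

    Timestamps are parsed to UTC; day-first dates ("13.12.2007 04:20") are
    accepted alongside ISO-8601.  Longitudes are normalized to (-180, 180]
    and classes validated against {0, 1, 2, 3}.
    """
    df = pd.read_csv(path_or_buf)
    missing = set(_FIX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fix table missing columns: {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    if ts.isna().any():
        ts = pd.to_datetime(df["timestamp"], utc=True, dayfirst=True)
    df = df.assign(timestamp=ts, lon=_normalize_lon(df["lon"]))
    return _validate_fixes(df)


def _validate_fixes(df: pd.DataFrame) -> pd.DataFrame:
    if not df["location_class"].isin(LOCATION_CLASSES).all():
        bad = sorted(set(df["location_class"]) - set(LOCATION_CLASSES))
        raise ValueError(f"invalid location classes: {bad}")
    if (df["lat"].abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    return df


def duty_cycle_index(timestamps: pd.Series) -> pd.Series:
    """Ordinal duty-cycle number of each fix (24 h windows from 01:00 GMT)."""
    anchor = pd.Timestamp("1970-01-01 01:00:00", tz="UTC")
    return ((timestamps - anchor) // pd.Timedelta(hours=24)).astype(int)


def select_daily_positions(fixes: pd.DataFrame) -> pd.DataFrame:
    """Keep the most accurate fix of each bird's duty cycle.

    The highest location class wins; ties go to the earliest fix.  Returns
    a DataFrame (bird_id, date, lon, lat, location_class) sorted by bird
    and date, with ``date`` the calendar day (UTC) the duty cycle started.
    """
    if fixes.empty:
        return pd.DataFrame(columns=["bird_id", "date", "lon", "lat",
                                     "location_class"])
    df = _validate_fixes(fixes.copy())
    df["_cycle"] = duty_cycle_index(df["timestamp"])
    df = df.sort_values(
        ["bird_id", "_cycle", "location_class", "timestamp"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = df.groupby(["bird_id", "_cycle"], as_index=False, sort=True).first()
    anchor = pd.Timestamp("1970-01-01 01:00:00", tz="UTC")
    best["date"] = (anchor + best["_cycle"] * pd.Timedelta(hours=24)).dt.date
    return best[["bird_id", "date", "lon", "lat", "location_class"]].reset_index(
        drop=True
    )


@dataclass
class MigrationSummary:
    """Migratory parameters for one bird."""

    bird_id: str
    colony: str
    deployment_date: date
    departure_date: date | None
    end_date: date
    duration_days: int
    n_daily_positions: int
    max_distance_colony_km: float | None
    min_distance_covered_km: float | None
    mean_daily_km: float | None
    sd_daily_km: float | None
    max_daily_km: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def migration_summary(
    daily: pd.DataFrame,
    colony_lonlat: tuple[float, float],
    deployment_date: date,
    colony_name: str = "",
) -> MigrationSummary:
    """Summarize one bird's filtered track.

    Duration is whole days from the deployment date to the date of the
    last transmission.  Daily distances are great-circle distances between
    consecutive daily positions, regardless of gaps; the minimum distance
    covered is their sum.
    """
    if daily.empty:
        raise ValueError("no daily positions")
    d = daily.sort_values("date").reset_index(drop=True)
    bird = str(d["bird_id"].iloc[0])
    end = d["date"].iloc[-1]
    departure = d["date"].iloc[0]
    duration = (end - deployment_date).days

    dist_colony = great_circle_km(
        (d["lon"].to_numpy(), d["lat"].to_numpy()), colony_lonlat
    )
    max_col = float(np.max(dist_colony))

    if len(d) >= 2:
        seg = great_circle_km(
            (d["lon"].to_numpy()[:-1], d["lat"].to_numpy()[:-1]),
            (d["lon"].to_numpy()[1:], d["lat"].to_numpy()[1:]),
        )
        seg = np.atleast_1d(seg)
        mean_daily = float(seg.mean())
        sd_daily = float(seg.std(ddof=1)) if seg.size >= 2 else None
        stats = dict(
            min_distance_covered_km=float(seg.sum()),
            mean_daily_km=mean_daily,
            sd_daily_km=sd_daily,
            max_daily_km=float(seg.max()),
        )
    else:
        stats = dict(min_distance_covered_km=None, mean_daily_km=None,
                     sd_daily_km=None, max_daily_km=None)

    return MigrationSummary(
        bird_id=bird,
        colony=colony_name,
        deployment_date=deployment_date,
        departure_date=departure,
        end_date=end,
        duration_days=duration,
        n_daily_positions=len(d),
        max_distance_colony_km=max_col,
        **stats,
    )


_COHORT_PARAMS = [
    "duration_days",
    "max_distance_colony_km",
    "min_distance_covered_km",
    "mean_daily_km",
    "max_daily_km",
]


def cohort_stats(summaries: pd.DataFrame, group: str | None = None) -> pd.Series:
    """Mean, sample sd (n-1) and totals of the migratory parameters.

    ``summaries`` is a DataFrame with one row per bird (as produced by
    :class:`MigrationSummary` rows or the reference cohort table).  When
    ``group`` is given only that colony's rows are used.  With a single
    bird the sd is reported as missing, not 0.
    """
    df = summaries if group is None else summaries[summaries["colony"] == group]
    if df.empty:
        raise ValueError(f"no summaries for group {group!r}")
    out: dict[str, float] = {"n_birds": float(len(df))}
    for p in _COHORT_PARAMS:
        if p not in df.columns:
            continue
        vals = pd.to_numeric(df[p], errors="coerce").dropna().to_numpy(float)
        if vals.size == 0:
            continue
        out[f"{p}_mean"] = float(vals.mean())
        out[f"{p}_sd"] = float(vals.std(ddof=1)) if vals.size >= 2 else np.nan
        out[f"{p}_total"] = float(vals.sum())
    return pd.Series(out)


def _parse_dmy(s: pd.Series) -> pd.Series:
    """Parse the field dialect '13.12.2007' (day.month.year)."""
    return pd.to_datetime(s, format="%d.%m.%Y").dt.date


def load_reference_cohort() -> pd.DataFrame:
    """Published migratory summaries for the 18 king penguin fledglings
    satellite-tracked from the Falkland Islands (FI, Volunteer Beach,
    deployed 11 Dec 2007) and South Georgia (SG, St Andrews Bay, deployed
    13 Dec 2007).

    Dates in the source table use the day.month.year dialect; they are
    returned as ``datetime.date``.
    """
    ref = importlib.resources.files("pengdisp.data") / "fledgling_cohort_2007.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    for col in ("deployment_date", "departure_date", "end_date"):
        df[col] = _parse_dmy(df[col])
    return df


def duration_days(deployment: date, end: date) -> int:
    """Whole days from deployment to last transmission."""
    return (end - deployment).days
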