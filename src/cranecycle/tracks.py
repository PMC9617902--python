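"""Reading, filtering and regularizing tracking fixes.

Fixes are carried as a pandas DataFrame with columns
``id, timestamp, lon, lat, loc_error_m`` (the track schema).  ``timestamp``
is timezone-naive UTC; coordinates are WGS84 decimal degrees;
``loc_error_m`` is the device-reported location error in metres and may be
missing (NaN).  A *trajectory* is the sub-frame for one individual, sorted
by time with strictly increasing timestamps.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: IUGG mean Earth radius, km.  Fixed so distances are bit-reproducible.
EARTH_RADIUS_KM = 6371.0088

TRACK_COLUMNS = ["id", "timestamp", "lon", "lat", "loc_error_m"]


class TrackFormatError(ValueError):
    """Raised when a tracks CSV does not conform to the track schema."""


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km on a sphere of radius 6371.0088 km.

    Accepts scalars or array-likes (broadcast).  Symmetric and satisfies the
    triangle inequality; identical points map to exactly 0.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding for near-antipodal pairs
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def read_tracks(path) -> pd.DataFrame:
    """Read a tracks CSV into the track schema.

    Rows are sorted by (id, timestamp); duplicate timestamps within an
    individual are collapsed to the first occurrence (logged).  Raises
    :class:`TrackFormatError` on missing columns and :class:`ValueError`
    naming the offending line for unparseable timestamps.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"tracks CSV missing required columns: {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = (df.index[bad] + 2).tolist()
        raise ValueError(f"unparseable timestamp(s) at CSV line(s) {lines[:10]}")
    df = df.assign(timestamp=ts.dt.tz_localize(None))
    df = df.sort_values(["id", "timestamp"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["id", "timestamp"])
    if dup.any():
        logger.warning("collapsing %d duplicate-timestamp fixes", int(dup.sum()))
        df = df[~dup].reset_index(drop=True)
    return df[TRACK_COLUMNS]


def filter_location_error(traj: pd.DataFrame, max_error_m: float = 100.0) -> pd.DataFrame:
    """Drop fixes whose location error strictly exceeds ``max_error_m``.

    Fixes with missing error are retained: only known-bad fixes are excluded.
    """
    err = traj["loc_error_m"]
    keep = err.isna() | (err <= max_error_m)
    return traj[keep].reset_index(drop=True)


def resample(traj: pd.DataFrame, interval_h: float = 2.0,
             tolerance_h: float = 0.25) -> pd.DataFrame:
    """Thin each trajectory to roughly one fix per ``interval_h`` hours.

    Greedy subset selection, no interpolation: keep the first fix, then
    repeatedly keep the earliest fix at least ``interval_h - tolerance_h``
    after the last kept fix.  Output rows are a subset of the input rows.
    """
    if interval_h <= 0:
        raise ValueError("interval_h must be positive")
    min_gap = pd.Timedelta(hours=interval_h - tolerance_h)

    def _one(g: pd.DataFrame) -> pd.DataFrame:
        t = g["timestamp"].to_numpy()
        keep = []
        last = None
        for i in range(len(t)):
            if last is None or t[i] - last >= min_gap:
                keep.append(i)
                last = t[i]
        return g.iloc[keep]

    out = pd.concat(
        [_one(g) for _, g in traj.groupby("id", sort=False)],
        ignore_index=True,
    ) if len(traj) else traj.copy()
    return out


def step_metrics(traj: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-fix step metrics for a single-individual trajectory.

    Returns a DataFrame with n-1 rows (empty for <2 fixes) and columns
    ``distance_km, dt_h, ground_speed_kmh``, where row i describes the step
    into fix i+1.
    """
    cols = ["distance_km", "dt_h", "ground_speed_kmh"]
    if len(traj) < 2:
        return pd.DataFrame(columns=cols)
    lon = traj["lon"].to_numpy()
    lat = traj["lat"].to_numpy()
    t = traj["timestamp"].to_numpy()
    dist = great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    dt_h = (t[1:] - t[:-1]) / np.timedelta64(1, "h")
    if np.any(dt_h <= 0):
        raise ValueError("timestamps must be strictly increasing within a trajectory")
    return pd.DataFrame({
        "distance_km": np.atleast_1d(dist),
        "dt_h": dt_h,
        "ground_speed_kmh": np.atleast_1d(dist) / dt_h,
    })


def preprocess(traj: pd.DataFrame, max_error_m: float = 100.0,
               interval_h: float = 2.0, tolerance_h: float = 0.25) -> pd.DataFrame:
    """Error filter then temporal thinning — the standard track pipeline head."""
    return resample(filter_location_error(traj, max_error_m), interval_h, tolerance_h)
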