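"""Region classification and migration-event extraction.

The annual range is split by two latitude thresholds: fixes strictly above
47°N are on the breeding grounds, fixes strictly below 29.3°N are on the
wintering grounds, everything else is transit.  A migration event is one
directed crossing between the two terminal regions; its departure date is
the UTC date of the last fix inside the origin region and its arrival date
the UTC date of the first fix inside the destination region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

BREEDING_LAT = 47.0
WINTERING_LAT = 29.3

EVENT_COLUMNS = ["id", "direction", "year", "departure_date", "arrival_date",
                 "duration_days", "n_stops"]


def classify_region(lat):
    """Label latitude(s) as ``breeding`` / ``wintering`` / ``transit``.

    Strict inequalities: exactly 47.0°N or 29.3°N is transit.
    """
    lat = np.asarray(lat, dtype=float)
    out = np.where(lat > BREEDING_LAT, "breeding",
                   np.where(lat < WINTERING_LAT, "wintering", "transit"))
    if out.ndim == 0:
        return str(out)
    return out


def extract_events(traj: pd.DataFrame) -> pd.DataFrame:
    """Extract complete migration events from one individual's trajectory.

    Scans the time-ordered fixes restricted to the two terminal regions;
    each breeding→wintering transition yields a southbound event and each
    wintering→breeding transition a northbound event.  Departure is the last
    terminal fix before the crossing, so brief dips across a threshold while
    still commuting within the origin region do not advance the departure.
    Incomplete journeys (never reaching the destination region) yield no
    event.  ``n_stops`` is left at NA; see
    :func:`cranecycle.stopover.assign_stops_to_events`.

    The season year of a southbound event is the calendar year of departure;
    of a northbound event, the calendar year of arrival.
    """
    ids = traj["id"].unique()
    if len(ids) > 1:
        return pd.concat(
            [extract_events(g) for _, g in traj.groupby("id", sort=False)],
            ignore_index=True,
        )
    region = classify_region(traj["lat"].to_numpy())
    terminal = region != "transit"
    sub = traj[terminal]
    labels = region[terminal]
    events = []
    cur_region = None
    cur_idx = None  # positional index of last fix in current terminal region
    for pos in range(len(sub)):
        lab = labels[pos]
        if cur_region is None or lab == cur_region:
            cur_region, cur_idx = lab, pos
            continue
        dep_ts = sub["timestamp"].iloc[cur_idx]
        arr_ts = sub["timestamp"].iloc[pos]
        direction = "southbound" if cur_region == "breeding" else "northbound"
        dep_date = dep_ts.normalize()
        arr_date = arr_ts.normalize()
        events.append({
            "id": sub["id"].iloc[pos],
            "direction": direction,
            "year": dep_date.year if direction == "southbound" else arr_date.year,
            "departure_date": dep_date,
            "arrival_date": arr_date,
            "duration_days": int((arr_date - dep_date).days),
            "n_stops": pd.NA,
        })
        cur_region, cur_idx = lab, pos
    return pd.DataFrame(events, columns=EVENT_COLUMNS)


def summarize_events(events: pd.DataFrame,
                     by=("direction",)) -> pd.DataFrame:
    """Median/min/max/n of duration and departure/arrival day-of-year per group.

    ``by`` may be ``("direction",)`` or ``("direction", "year")``.  Groups
    with no events are simply absent.  The median uses the usual convention
    (mean of the central pair for even n).
    """
    if len(events) == 0:
        return pd.DataFrame()
    ev = events.copy()
    ev["departure_doy"] = pd.to_datetime(ev["departure_date"]).dt.dayofyear
    ev["arrival_doy"] = pd.to_datetime(ev["arrival_date"]).dt.dayofyear
    rows = []
    for key, g in ev.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        row = dict(zip(by, key))
        row["n"] = len(g)
        for col in ("duration_days", "departure_doy", "arrival_doy"):
            row[f"{col}_median"] = float(g[col].median())
            row[f"{col}_min"] = float(g[col].min())
            row[f"{col}_max"] = float(g[col].max())
        rows.append(row)
    return pd.DataFrame(rows)


def minimum_convex_polygon(lon, lat) -> np.ndarray:
    """100% minimum convex polygon of a point set.

    Returns the hull vertices as an (m, 2) ``[lon, lat]`` array in
    counter-clockwise order.  All points are included (no peeling).  Fewer
    than 3 points, or a collinear set, raises ``ValueError``.
    """
    pts = np.column_stack([np.asarray(lon, float), np.asarray(lat, float)])
    if len(pts) < 3:
        raise ValueError("minimum convex polygon needs at least 3 fixes")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise ValueError(f"degenerate geometry (collinear or coincident fixes): {e}") from e
    return pts[hull.vertices]  # Qhull returns 2-D hull vertices CCW
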