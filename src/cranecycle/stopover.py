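"""Stationary-fix screening and stopover-site clustering.

A migrating bird's staging sites are found by (1) keeping fixes whose
incoming step is short (<10 km) and effectively zero-speed, (2) excluding
the breeding and wintering regions, (3) agglomerative clustering of the
remaining fixes on the great-circle distance matrix with the tree cut at
50 km, and (4) keeping clusters where the bird stayed at least two days.
Complete linkage guarantees every within-cluster pairwise distance is below
the cut.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .phenology import classify_region
from .tracks import great_circle_km, step_metrics

CLUSTER_COLUMNS = ["cluster_id", "individual_id", "lon", "lat",
                   "first_seen", "last_seen", "dwell_days", "n_fixes"]


def stationary_fixes(traj: pd.DataFrame, max_step_km: float = 10.0,
                     speed_epsilon: float = 0.1) -> pd.DataFrame:
    """Subset of fixes classified as stationary.

    A fix is stationary when its incoming step covers strictly less than
    ``max_step_km`` and its ground speed is at most ``speed_epsilon`` km/h
    (``speed_epsilon=0`` recovers the strict zero-speed rule, which noisy
    GPS never satisfies).  The first fix of a trajectory has no incoming
    step and is assessed by its outgoing step instead.
    """
    parts = []
    for _, g in traj.groupby("id", sort=False):
        if len(g) < 2:
            continue
        steps = step_metrics(g)
        ok = (steps["distance_km"].to_numpy() < max_step_km) & \
             (steps["ground_speed_kmh"].to_numpy() <= speed_epsilon)
        keep = np.concatenate([[ok[0]], ok])  # first fix: outgoing step
        parts.append(g[keep])
    if not parts:
        return traj.iloc[0:0]
    return pd.concat(parts, ignore_index=True)


def _complete_linkage_labels(lon, lat, cut_km, method):
    n = len(lon)
    if n == 1:
        return np.array([1])
    dm = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(dm, 0.0)
    Z = scipy_linkage(squareform(dm, checks=False), method=method)
    return fcluster(Z, t=cut_km, criterion="distance")


def _split_visits(times: pd.Series, gap_days: float):
    """Split a sorted timestamp series into contiguous visits at large gaps."""
    t = times.sort_values().to_numpy()
    if len(t) == 0:
        return []
    gaps = np.diff(t) / np.timedelta64(1, "D")
    breaks = np.nonzero(gaps > gap_days)[0]
    bounds = np.concatenate([[0], breaks + 1, [len(t)]])
    return [(t[a], t[b - 1], b - a) for a, b in zip(bounds[:-1], bounds[1:])]


def cluster_stationary(fixes: pd.DataFrame, cut_km: float = 50.0,
                       linkage: str = "complete",
                       exclude=("breeding", "wintering"),
                       pooled: bool = False,
                       visit_gap_days: float = 1.0) -> pd.DataFrame:
    """Cluster stationary fixes into candidate stopover sites.

    Fixes inside the excluded regions are dropped first.  Clustering is
    agglomerative on the pairwise great-circle distance matrix with the
    dendrogram cut at ``cut_km``; the default complete linkage bounds every
    within-cluster pairwise distance by the cut.  ``pooled=True`` clusters
    all individuals together (site-level view); the default clusters per
    individual.

    A bird may pass the same site on both legs of the annual round trip, so
    a spatial cluster's member fixes are split into temporally contiguous
    *visits* wherever consecutive member fixes are more than
    ``visit_gap_days`` apart.  Per-individual mode emits one row per visit
    (centroid = mean of member coordinates, dwell = last − first seen, in
    fractional days).  Pooled mode emits one row per site: ``dwell_days``
    is the longest single visit and ``mean_stay_days`` the mean over all
    individuals' visits.
    """
    if len(fixes) == 0:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    region = classify_region(fixes["lat"].to_numpy())
    fixes = fixes[~np.isin(region, list(exclude))]
    if len(fixes) == 0:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)

    groups = [("pooled", fixes)] if pooled else list(fixes.groupby("id", sort=False))
    rows = []
    next_id = 0
    for gid, g in groups:
        labels = _complete_linkage_labels(
            g["lon"].to_numpy(), g["lat"].to_numpy(), cut_km, linkage)
        for lab in np.unique(labels):
            m = g[labels == lab]
            base = {
                "lon": float(m["lon"].mean()),
                "lat": float(m["lat"].mean()),
            }
            if pooled:
                stays = []
                for _, mi in m.groupby("id", sort=False):
                    stays.extend(_split_visits(mi["timestamp"], visit_gap_days))
                dwells = [(b - a) / np.timedelta64(1, "D") for a, b, _ in stays]
                rows.append({
                    "cluster_id": next_id, "individual_id": pd.NA, **base,
                    "first_seen": m["timestamp"].min(),
                    "last_seen": m["timestamp"].max(),
                    "n_fixes": len(m),
                    "dwell_days": float(max(dwells)),
                    "mean_stay_days": float(np.mean(dwells)),
                    "n_individuals": m["id"].nunique(),
                })
                next_id += 1
            else:
                for a, b, nfix in _split_visits(m["timestamp"], visit_gap_days):
                    rows.append({
                        "cluster_id": next_id, "individual_id": gid, **base,
                        "first_seen": pd.Timestamp(a), "last_seen": pd.Timestamp(b),
                        "n_fixes": nfix,
                        "dwell_days": float((b - a) / np.timedelta64(1, "D")),
                    })
                    next_id += 1
    return pd.DataFrame(rows)


def pool_sites(visits: pd.DataFrame, cut_km: float = 50.0,
               linkage: str = "complete") -> pd.DataFrame:
    """Aggregate per-individual visit clusters into shared sites.

    Clusters the visit *centroids* across individuals with the same
    great-circle complete-linkage cut — a two-stage pooling that stays
    memory-light at many-individual scale while preserving the 50-km
    proximity rule.  A site's ``dwell_days`` is its longest single visit
    and ``mean_stay_days`` the mean over visits, so the usual dwell filter
    (:func:`stopovers`) applies unchanged.
    """
    if len(visits) == 0:
        return pd.DataFrame(columns=["site_id", "lon", "lat", "n_visits",
                                     "n_individuals", "dwell_days",
                                     "mean_stay_days"])
    labels = _complete_linkage_labels(
        visits["lon"].to_numpy(), visits["lat"].to_numpy(), cut_km, linkage)
    rows = []
    for sid, lab in enumerate(np.unique(labels)):
        m = visits[labels == lab]
        rows.append({
            "site_id": sid,
            "lon": float(m["lon"].mean()), "lat": float(m["lat"].mean()),
            "n_visits": len(m),
            "n_individuals": m["individual_id"].nunique(),
            "dwell_days": float(m["dwell_days"].max()),
            "mean_stay_days": float(m["dwell_days"].mean()),
        })
    return pd.DataFrame(rows)


def stopovers(clusters: pd.DataFrame, min_days: float = 2.0) -> pd.DataFrame:
    """Keep clusters with dwell of at least ``min_days`` days (true stopovers)."""
    if len(clusters) == 0:
        return clusters
    return clusters[clusters["dwell_days"] >= min_days].reset_index(drop=True)


def assign_stops_to_events(events: pd.DataFrame, stops: pd.DataFrame) -> pd.DataFrame:
    """Fill each migration event's ``n_stops`` from per-individual stopovers.

    A stopover counts toward the event whose [departure, arrival] window
    contains its ``first_seen`` instant (so a stay straddling the arrival
    date belongs to the event in which it began).
    """
    events = events.copy()
    counts = []
    for _, ev in events.iterrows():
        if len(stops) == 0:
            counts.append(0)
            continue
        mine = stops[stops["individual_id"] == ev["id"]]
        t0 = pd.Timestamp(ev["departure_date"])
        t1 = pd.Timestamp(ev["arrival_date"]) + pd.Timedelta(days=1)  # whole arrival day
        counts.append(int(((mine["first_seen"] >= t0) & (mine["first_seen"] < t1)).sum()))
    events["n_stops"] = counts
    return events


class StopoverDetector(BaseEstimator):
    """Stationary-fix screening plus hierarchical stopover clustering.

    Parameters
    ----------
    cut_km : float, default 50.0
        Dendrogram cut height; complete linkage makes it a bound on every
        within-cluster pairwise great-circle distance.
    min_days : float, default 2.0
        Minimum dwell for a cluster to count as a true stopover site.
    max_step_km : float, default 10.0
        Strict upper bound on the incoming step of a stationary fix.
    speed_epsilon : float, default 0.1
        Ground-speed tolerance (km/h) standing in for "zero ground speed".
    linkage : {"complete", "single"}, default "complete"
    pooled : bool, default False
        Cluster all individuals together (site counts) instead of per bird.

    Attributes
    ----------
    stationary_ : DataFrame of stationary fixes outside the terminal regions.
    clusters_ : DataFrame of all clusters (pre-dwell-threshold).
    stopovers_ : DataFrame of clusters passing the dwell threshold.
    """

    def __init__(self, cut_km: float = 50.0, min_days: float = 2.0,
                 max_step_km: float = 10.0, speed_epsilon: float = 0.1,
                 linkage: str = "complete", pooled: bool = False,
                 visit_gap_days: float = 1.0):
        self.cut_km = cut_km
        self.min_days = min_days
        self.max_step_km = max_step_km
        self.speed_epsilon = speed_epsilon
        self.linkage = linkage
        self.pooled = pooled
        self.visit_gap_days = visit_gap_days

    def fit(self, traj: pd.DataFrame, y=None):
        """Run the screening/clustering pipeline on preprocessed fixes."""
        if self.linkage not in ("complete", "single"):
            raise ValueError("linkage must be 'complete' or 'single'")
        stat = stationary_fixes(traj, self.max_step_km, self.speed_epsilon)
        self.stationary_ = stat
        self.clusters_ = cluster_stationary(
            stat, cut_km=self.cut_km, linkage=self.linkage, pooled=self.pooled,
            visit_gap_days=self.visit_gap_days)
        self.stopovers_ = stopovers(self.clusters_, self.min_days)
        return self
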