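import numpy as np
import pandas as pd
import pytest

from cranecycle import stopover, synth, tracks
from cranecycle.tracks import great_circle_km
from conftest import exhaustive_complete_linkage


def transit_fixes(times_h, lons, lats, ind="b0"):
    return pd.DataFrame({
        "id": [ind] * len(lons),
        "timestamp": pd.Timestamp("2015-03-01") + pd.to_timedelta(times_h, unit="h"),
        "lon": lons, "lat": lats,
        "loc_error_m": [5.0] * len(lons),
    })


class TestStationaryFixes:
    def test_distance_thresholds(self):
        # steps of 9.9, 10.0 km along a meridian at 2-h spacing, crawling speed
        lat0 = 40.0
        step_deg = np.array([0.0, 9.9, 10.0]) / 111.195
        lats = lat0 + np.cumsum(step_deg)
        t = transit_fixes([0, 100, 200], [110.0] * 3, lats)
        out = stopover.stationary_fixes(t, speed_epsilon=0.2)
        # 9.9 km step over 100 h -> speed 0.099, eligible; 10.0 km step excluded
        assert len(out) == 2

    def test_speed_epsilon_excludes_slow_drift(self):
        # 1 km over 2 h = 0.5 km/h > epsilon 0.1
        lats = [40.0, 40.0 + 1.0 / 111.195]
        t = transit_fixes([0, 2], [110.0, 110.0], lats)
        assert len(stopover.stationary_fixes(t, speed_epsilon=0.1)) == 0

    def test_first_fix_uses_outgoing_step(self):
        t = transit_fixes([0, 2, 4], [110.0, 110.0, 115.0], [40.0, 40.0, 40.0])
        out = stopover.stationary_fixes(t)
        # first two coincident fixes stationary, third is a 400+ km jump
        assert len(out) == 2


class TestClusterStationary:
    def two_points_km_apart(self, km):
        dlat = km / 111.195
        return transit_fixes([0, 12], [110.0, 110.0], [40.0, 40.0 + dlat])

    def test_49_km_one_cluster(self):
        cl = stopover.cluster_stationary(self.two_points_km_apart(49.0))
        assert len(cl) == 1

    def test_51_km_two_clusters(self):
        cl = stopover.cluster_stationary(self.two_points_km_apart(51.0))
        assert len(cl) == 2

    def test_single_fix_singleton(self):
        t = transit_fixes([0], [110.0], [40.0])
        cl = stopover.cluster_stationary(t)
        assert len(cl) == 1
        assert cl["n_fixes"].iloc[0] == 1

    def test_terminal_regions_excluded(self):
        t = transit_fixes([0, 2, 4], [110.0] * 3, [48.0, 40.0, 28.0])
        cl = stopover.cluster_stationary(t)
        assert len(cl) == 1
        assert cl["lat"].iloc[0] == 40.0

    def test_empty_input(self):
        t = transit_fixes([], [], [])
        assert len(stopover.cluster_stationary(t)) == 0

    def test_complete_linkage_bound_holds(self):
        rng = np.random.default_rng(3)
        n = 60
        t = transit_fixes(np.arange(n) * 2.0, 110 + rng.uniform(0, 3, n),
                          38 + rng.uniform(0, 3, n))
        labels = stopover._complete_linkage_labels(
            t["lon"].to_numpy(), t["lat"].to_numpy(), 50.0, "complete")
        for lab in np.unique(labels):
            m = t[labels == lab]
            lon, lat = m["lon"].to_numpy(), m["lat"].to_numpy()
            dm = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
            assert dm.max() <= 50.0 + 1e-9

    def test_matches_exhaustive_oracle_small_sets(self):
        rng = np.random.default_rng(17)
        for rep in range(30):
            n = int(rng.integers(2, 13))
            lon = 105 + rng.uniform(0, 4, n)
            lat = 33 + rng.uniform(0, 4, n)
            labels = stopover._complete_linkage_labels(lon, lat, 50.0, "complete")
            ours = {frozenset(np.nonzero(labels == lab)[0].tolist())
                    for lab in np.unique(labels)}
            dm = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
            np.fill_diagonal(dm, 0.0)
            oracle = {frozenset(c) for c in exhaustive_complete_linkage(dm, 50.0)}
            assert ours == oracle


class TestStopovers:
    def make_clusters(self, dwells):
        return pd.DataFrame({
            "cluster_id": range(len(dwells)),
            "individual_id": ["b0"] * len(dwells),
            "lon": 110.0, "lat": 40.0,
            "first_seen": pd.Timestamp("2015-03-01"),
            "last_seen": [pd.Timestamp("2015-03-01") + pd.Timedelta(days=d)
                          for d in dwells],
            "dwell_days": dwells, "n_fixes": 10,
        })

    def test_threshold(self):
        out = stopover.stopovers(self.make_clusters([2.5, 1.99, 2.0]))
        assert out["dwell_days"].tolist() == [2.5, 2.0]

    def test_empty(self):
        assert len(stopover.stopovers(self.make_clusters([]))) == 0

    def test_monotone_in_min_days(self):
        cl = self.make_clusters(list(np.linspace(0, 10, 21)))
        counts = [len(stopover.stopovers(cl, min_days=d)) for d in (0, 1, 2, 5, 8)]
        assert counts == sorted(counts, reverse=True)


class TestAssignStops:
    def test_zero_noise_truth_counts(self, clean_tracks):
        from cranecycle import phenology
        _, tracks_df, truth = clean_tracks
        det = stopover.StopoverDetector().fit(tracks_df)
        ev = stopover.assign_stops_to_events(
            phenology.extract_events(tracks_df), det.stopovers_)
        # truth: dwell >= 2 days observable at the 2-h fix interval
        margin = 2.0 + 2.0 / 24.0
        expected = (truth["stopovers"][truth["stopovers"]["dwell_days"] >= margin]
                    .groupby(["id", "direction", "year"]).size())
        for _, e in ev.iterrows():
            assert e["n_stops"] == expected.get((e["id"], e["direction"], e["year"]), 0)

    def test_no_stationary_fixes_zero_stops(self):
        ev = pd.DataFrame({
            "id": ["b0"], "direction": ["southbound"], "year": [2015],
            "departure_date": [pd.Timestamp("2015-09-20")],
            "arrival_date": [pd.Timestamp("2015-10-20")],
            "duration_days": [30], "n_stops": [pd.NA],
        })
        out = stopover.assign_stops_to_events(ev, pd.DataFrame())
        assert out["n_stops"].iloc[0] == 0

    def test_straddling_stop_assigned_by_first_seen(self):
        ev = pd.DataFrame({
            "id": ["b0"], "direction": ["southbound"], "year": [2015],
            "departure_date": [pd.Timestamp("2015-09-20")],
            "arrival_date": [pd.Timestamp("2015-10-20")],
            "duration_days": [30], "n_stops": [pd.NA],
        })
        stops = pd.DataFrame({
            "cluster_id": [0], "individual_id": ["b0"],
            "lon": [110.0], "lat": [40.0],
            "first_seen": [pd.Timestamp("2015-10-19")],
            "last_seen": [pd.Timestamp("2015-10-25")],
            "dwell_days": [6.0], "n_fixes": [50],
        })
        out = stopover.assign_stops_to_events(ev, stops)
        assert out["n_stops"].iloc[0] == 1


class TestPoolSites:
    def test_shared_site_aggregated_across_individuals(self):
        visits = pd.DataFrame({
            "cluster_id": [0, 1, 2],
            "individual_id": ["b0", "b1", "b1"],
            "lon": [116.80, 116.81, 113.0],
            "lat": [41.80, 41.81, 33.0],
            "first_seen": pd.Timestamp("2015-10-01"),
            "last_seen": pd.Timestamp("2015-10-05"),
            "dwell_days": [14.0, 12.0, 1.0],
            "n_fixes": 50,
        })
        sites = stopover.pool_sites(visits)
        assert len(sites) == 2
        luan = sites[sites["lat"] > 40].iloc[0]
        assert luan["n_individuals"] == 2
        assert luan["dwell_days"] == 14.0
        assert luan["mean_stay_days"] == pytest.approx(13.0)

    def test_empty(self):
        assert len(stopover.pool_sites(pd.DataFrame())) == 0


class TestDetectorEstimator:
    def test_sklearn_params_roundtrip(self):
        det = stopover.StopoverDetector(cut_km=40.0)
        assert det.get_params()["cut_km"] == 40.0
        det.set_params(min_days=3.0)
        assert det.min_days == 3.0

    def test_invalid_linkage_rejected(self):
        with pytest.raises(ValueError, match="linkage"):
            stopover.StopoverDetector(linkage="ward").fit(
                transit_fixes([0, 2], [110, 110], [40, 40]))
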