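import numpy as np
import pandas as pd
import pytest

from cranecycle import synth

# Three well-separated transit-band staging sites with multi-day planned
# dwells; used by the stopover-recovery tests and kept >50 km apart so the
# clustering cut cannot merge them.
RECOVERY_SITES = (
    ((116.8, 41.8), 14.0),
    ((115.5, 36.5), 4.0),
    ((113.0, 33.0), 3.0),
)


def recovery_track_config(seed: int, gps_noise_m: float) -> synth.TrackSimConfig:
    return synth.TrackSimConfig(
        n_individuals=1,
        years=(2015,),
        stopover_sites=RECOVERY_SITES,
        gps_noise_m=gps_noise_m,
        argos_fraction=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_tracks():
    """Two individuals, one annual round trip, zero position noise."""
    cfg = synth.TrackSimConfig(n_individuals=2, years=(2014,), gps_noise_m=0.0,
                               argos_fraction=0.0, seed=11)
    tracks, truth = synth.simulate_tracks(cfg)
    return cfg, tracks, truth


@pytest.fixture(scope="session")
def small_histories():
    cfg = synth.CJSSimConfig(
        n_juveniles=30, n_adults=5, p_year=0.5,
        occasions=(2013, 2014, 2015, 2016, 2017), seed=7)
    return cfg, synth.simulate_capture_histories(cfg)


def brute_force_hull(points: np.ndarray) -> set:
    """O(n^3) convex-hull membership test: a point is a hull vertex iff some
    edge through it has all other points strictly on one side."""
    n = len(points)
    hull = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = points[j] - points[i]
            rel = points - points[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            others = np.delete(cross, [i, j])
            if np.all(others > 0) or np.all(others < 0):
                hull.add(i)
                hull.add(j)
    return hull


def exhaustive_complete_linkage(dm: np.ndarray, cut: float) -> list:
    """Naive agglomeration oracle: repeatedly merge the closest pair of
    clusters under complete linkage while the merge height is <= cut."""
    clusters = [{i} for i in range(len(dm))]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dm[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        if best[0] > cut:
            break
        d, a, b = best
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return clusters


def enumerate_cjs_probability(h, first, phi, p):
    """Brute-force CJS likelihood: sum over every latent alive/dead path.

    Because death is an absorbing state a path is determined by the first
    dead occasion d (d = K means alive throughout the study).
    """
    K = len(h)
    total = 0.0
    for d in range(first + 1, K + 1):
        alive = [t < d for t in range(K)]
        prob = 1.0
        valid = True
        for t in range(first, K - 1):
            if alive[t]:
                prob *= phi[t] if alive[t + 1] else (1.0 - phi[t])
        for t in range(first + 1, K):
            if h[t] == 1:
                if not alive[t]:
                    valid = False
                    break
                prob *= p[t - 1]
            elif alive[t]:
                prob *= 1.0 - p[t - 1]
        if valid:
            total += prob
    return total
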