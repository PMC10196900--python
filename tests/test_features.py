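import math

import numpy as np
import pandas as pd
import pytest

from drinksense.events import WindowConfig
from drinksense.features import (
    CM_FLOOR,
    FEATURE_NAMES,
    FEATURE_REGISTRY,
    TIME_ENCODINGS,
    ParticipantData,
    accel_features,
    circadian_band_energy,
    circadian_movement,
    cluster_places,
    comm_features,
    device_features,
    haversine_m,
    location_entropy,
    location_variance,
    radius_of_gyration,
    stay_points,
    significant_places,
    travel_distance,
    wifi_feature,
    window_features,
)
from drinksense.timeutil import DAY_S, HOUR_S

from conftest import gps_frame, one_participant_streams

R_EARTH = 6_371_000.0
LAT0, LON0 = 40.44, -80.0


# ---------------------------------------------------------------------------
# independent scalar oracles (plain math, no vectorization)


def hav_oracle(a, b):
    la1, lo1 = math.radians(a[0]), math.radians(a[1])
    la2, lo2 = math.radians(b[0]), math.radians(b[1])
    h = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * R_EARTH * math.asin(math.sqrt(h))


def rog_oracle(pts):
    cy = sum(p[0] for p in pts) / len(pts)
    cx = sum(p[1] for p in pts) / len(pts)
    return math.sqrt(sum(hav_oracle(p, (cy, cx)) ** 2 for p in pts) / len(pts))


def var_oracle(pts):
    lats = [p[0] for p in pts]
    lons = [p[1] for p in pts]

    def pvar(v):
        m = sum(v) / len(v)
        return sum((x - m) ** 2 for x in v) / len(v)

    return pvar(lats) + pvar(lons)


def entropy_oracle(dwell):
    tot = sum(dwell)
    return -sum((d / tot) * math.log(d / tot) for d in dwell if d > 0)


def travel_oracle(pts):
    return sum(hav_oracle(pts[i], pts[i + 1]) for i in range(len(pts) - 1))


def ls_energy_oracle(t, y, band_h=(23.5, 24.5), n_freq=25):
    """Textbook normalized Lomb periodogram integrated over the band."""
    ybar = sum(y) / len(y)
    yc = [v - ybar for v in y]
    ss_half = sum(v * v for v in yc) / 2
    if ss_half == 0:
        return 0.0
    periods = [band_h[0] * 3600 + i * (band_h[1] - band_h[0]) * 3600 / (n_freq - 1)
               for i in range(n_freq)]
    powers = []
    for T in periods:
        w = 2 * math.pi / T
        s2 = sum(math.sin(2 * w * ti) for ti in t)
        c2 = sum(math.cos(2 * w * ti) for ti in t)
        tau = math.atan2(s2, c2) / (2 * w)
        cs = [math.cos(w * (ti - tau)) for ti in t]
        sn = [math.sin(w * (ti - tau)) for ti in t]
        num_c = sum(v * c for v, c in zip(yc, cs)) ** 2 / sum(c * c for c in cs)
        num_s = sum(v * s for v, s in zip(yc, sn)) ** 2 / sum(s * s for s in sn)
        powers.append(0.5 * (num_c + num_s) / ss_half)
    freqs = [1.0 / T for T in periods]
    pairs = sorted(zip(freqs, powers))
    e = 0.0
    for (f1, p1), (f2, p2) in zip(pairs[:-1], pairs[1:]):
        e += 0.5 * (p1 + p2) * (f2 - f1)
    return e


def accel_oracle(t, mags):
    by_minute = {}
    for ti, m in zip(t, mags):
        by_minute.setdefault(int(ti // 60), []).append(m)
    means = sorted(
        (sum(v) / len(v) for v in by_minute.values()), reverse=False
    )
    n = len(means)
    mean = sum(means) / n
    med = (means[n // 2] if n % 2 else 0.5 * (means[n // 2 - 1] + means[n // 2]))
    std = math.sqrt(sum((m - mean) ** 2 for m in means) / n)
    return mean, med, std, max(means), min(means)


def _rand_pts(rng, n):
    return [
        (LAT0 + rng.uniform(-0.05, 0.05), LON0 + rng.uniform(-0.05, 0.05))
        for _ in range(n)
    ]


def test_formula_features_match_brute_force_on_random_inputs():
    """r_g, variance, entropy, travel distance and circadian band energy
    match independent scalar oracles to 1e-6 relative on 100 random
    inputs."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        pts = _rand_pts(rng, int(rng.integers(2, 12)))
        lat = np.array([p[0] for p in pts])
        lon = np.array([p[1] for p in pts])
        assert radius_of_gyration(lat, lon) == pytest.approx(rog_oracle(pts), rel=1e-6)
        assert location_variance(lat, lon) == pytest.approx(var_oracle(pts), rel=1e-6)
        assert travel_distance(lat, lon) == pytest.approx(travel_oracle(pts), rel=1e-6)
        dwell = rng.uniform(0.1, 10, int(rng.integers(1, 6)))
        assert location_entropy(dwell) == pytest.approx(
            entropy_oracle(list(dwell)), rel=1e-6, abs=1e-12
        )
        t = np.sort(rng.uniform(0, 3 * DAY_S, int(rng.integers(30, 60))))
        y = rng.normal(0, 1, len(t))
        assert circadian_band_energy(t, y) == pytest.approx(
            ls_energy_oracle(list(t), list(y)), rel=1e-6
        )


def test_accel_two_stage_matches_oracle():
    rng = np.random.default_rng(1)
    t = np.sort(rng.uniform(0, 900, 40))
    mags = rng.uniform(0.1, 3, 40)
    by_minute = (t // 60).astype(int)
    # package path: build per-minute means then stats
    import numpy as _np

    uniq, inv = _np.unique(by_minute, return_inverse=True)
    means = _np.bincount(inv, weights=mags) / _np.bincount(inv)
    got = accel_features(means)
    mean, med, std, mx, mn = accel_oracle(t, mags)
    assert got["accel_mag_mean"] == pytest.approx(mean, rel=1e-6)
    assert got["accel_mag_median"] == pytest.approx(med, rel=1e-6)
    assert got["accel_mag_std"] == pytest.approx(std, rel=1e-6)
    assert got["accel_mag_max"] == pytest.approx(mx, rel=1e-6)
    assert got["accel_mag_min"] == pytest.approx(mn, rel=1e-6)


def test_accel_trivial_cases():
    assert accel_features(np.array([9.81])) == pytest.approx(
        {
            "accel_mag_mean": 9.81,
            "accel_mag_median": 9.81,
            "accel_mag_std": 0.0,
            "accel_mag_max": 9.81,
            "accel_mag_min": 9.81,
            "accel_active_frac": 1.0,
        }
    )
    got = accel_features(np.array([1.0, 3.0]))
    assert got["accel_mag_mean"] == 2.0
    assert got["accel_mag_max"] == 3.0
    assert all(np.isnan(v) for v in accel_features(np.empty(0)).values())


def _offset(lat0, lon0, north_m, east_m):
    lat = lat0 + math.degrees(north_m / R_EARTH)
    lon = lon0 + math.degrees(east_m / (R_EARTH * math.cos(math.radians(lat0))))
    return lat, lon


def test_radius_of_gyration_constructions():
    assert radius_of_gyration([40.0, 40.0], [-80.0, -80.0]) == 0.0
    a = (LAT0, LON0)
    b = _offset(LAT0, LON0, 0, 200)
    lat = np.array([a[0], b[0]])
    lon = np.array([a[1], b[1]])
    assert radius_of_gyration(lat, lon) == pytest.approx(100.0, abs=0.1)
    # n points on a circle of radius R -> r_g = R
    R = 500.0
    pts = [_offset(LAT0, LON0, R * math.cos(th), R * math.sin(th))
           for th in np.linspace(0, 2 * math.pi, 12, endpoint=False)]
    assert radius_of_gyration(
        np.array([p[0] for p in pts]), np.array([p[1] for p in pts])
    ) == pytest.approx(R, rel=2e-3)


def test_travel_distance_and_scaling():
    a = (LAT0, LON0)
    b = _offset(LAT0, LON0, 1000, 0)
    assert travel_distance([a[0], b[0]], [a[1], b[1]]) == pytest.approx(1000, abs=1)
    # uniform dilation about the centroid scales r_g and travel linearly
    rng = np.random.default_rng(3)
    lat = LAT0 + rng.uniform(-0.01, 0.01, 8)
    lon = LON0 + rng.uniform(-0.01, 0.01, 8)
    lat2 = lat.mean() + 2 * (lat - lat.mean())
    lon2 = lon.mean() + 2 * (lon - lon.mean())
    assert radius_of_gyration(lat2, lon2) == pytest.approx(
        2 * radius_of_gyration(lat, lon), rel=1e-3
    )
    assert travel_distance(lat2, lon2) == pytest.approx(
        2 * travel_distance(lat, lon), rel=1e-3
    )


def test_location_entropy_identities():
    assert location_entropy([5.0]) == 0.0
    assert location_entropy([2.0, 2.0, 2.0, 2.0]) == pytest.approx(math.log(4))
    assert location_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)
    assert np.isnan(location_entropy([0.0, 0.0]))


def test_location_variance_identities():
    assert location_variance([1.0, 1.0], [2.0, 2.0]) == 0.0
    assert location_variance([0.0, 0.02], [0.0, 0.0]) == pytest.approx(1e-4)
    lat = np.array([0.1, 0.3, 0.7])
    lon = np.array([-1.0, -1.2, -0.8])
    assert location_variance(lat + 5, lon - 3) == pytest.approx(
        location_variance(lat, lon), rel=1e-9
    )
    assert np.isnan(location_variance([1.0], [1.0]))


def test_circadian_movement_discriminates_24h_rhythm():
    rng = np.random.default_rng(3)
    t = np.sort(rng.uniform(0, 3 * DAY_S, 200))
    sine = 0.01 * np.sin(2 * np.pi * t / DAY_S)
    noise = rng.normal(0, np.std(sine), len(t))
    lon = np.full(len(t), LON0)
    cm_sine = circadian_movement(t, LAT0 + sine, lon)
    cm_noise = circadian_movement(t, LAT0 + noise, lon)
    assert cm_sine > cm_noise
    # a 12-h rhythm leaves little energy in the 23.5-24.5 h band
    half = 0.01 * np.sin(2 * np.pi * t / (DAY_S / 2))
    e24 = circadian_band_energy(t, sine)
    e12 = circadian_band_energy(t, half)
    assert e12 < 0.10 * e24


def test_circadian_movement_degenerate_inputs():
    t = np.linspace(0, 2 * DAY_S, 100)
    flat = np.full(100, LAT0)
    assert circadian_movement(t, flat, flat) == pytest.approx(math.log(CM_FLOOR))
    short = np.linspace(0, 3 * HOUR_S, 50)
    assert np.isnan(circadian_movement(short, flat[:50], flat[:50]))


# ---------------------------------------------------------------------------
# significant places


def _shuttle_trajectory(n_cycles=4, sep_m=1000.0):
    """Dwell at A, hop to B, dwell, return — with 1-min fixes."""
    A = (LAT0, LON0)
    B = _offset(LAT0, LON0, sep_m, 0)
    t, lat, lon = [], [], []
    clock = 0.0
    for _ in range(n_cycles):
        for p in (A, B):
            for _ in range(30):  # 30 min dwell
                t.append(clock)
                lat.append(p[0] + np.random.default_rng(int(clock)).normal(0, 1e-5))
                lon.append(p[1])
                clock += 60
    return np.array(t), np.array(lat), np.array(lon)


def test_two_anchor_trajectory_recovers_two_places():
    t, lat, lon = _shuttle_trajectory()
    places, home = significant_places(t, lat, lon)
    assert len(places) == 2
    d = haversine_m(places["lat"].iloc[0], places["lon"].iloc[0],
                    places["lat"].iloc[1], places["lon"].iloc[1])
    assert d == pytest.approx(1000, abs=50)


def test_single_anchor_trajectory_one_place_full_dwell():
    t = np.arange(0, 6 * HOUR_S, 60.0)
    lat = np.full(len(t), LAT0)
    lon = np.full(len(t), LON0)
    stays = stay_points(t, lat, lon)
    assert len(stays) == 1
    assert stays["dwell_s"].iloc[0] == pytest.approx(6 * HOUR_S, abs=120)
    places, _ = significant_places(t, lat, lon)
    assert len(places) == 1


def test_tighter_clustering_never_reduces_place_count():
    t, lat, lon = _shuttle_trajectory(sep_m=300.0)
    stays = stay_points(t, lat, lon, dist_m=150)
    counts = [len(cluster_places(stays, merge_m=m)) for m in (800, 400, 200, 100)]
    assert all(b >= a for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# event-stream features


def test_comm_features_counting():
    empty = comm_features(np.array([]), np.array([]), np.array([]))
    assert all(v == 0 for v in empty.values())
    got = comm_features(
        np.array(["call_in", "call_in", "sms"]),
        np.array([60.0, 90.0, 0.0]),
        np.array(["c1", "c1", "c2"]),
    )
    assert got["n_calls_in"] == 2
    assert got["call_dur_in_s"] == 150
    assert got["call_dur_total_s"] == 150
    assert got["n_sms"] == 1
    assert got["n_call_contacts"] == 1  # same contact twice
    assert got["n_contacts"] == 2


def test_device_screen_and_app_features():
    t = np.array([10.0, 310.0, 400.0, 500.0, 600.0])
    kind = np.array(["screen_on", "screen_off", "app_foreground",
                     "app_foreground", "app_foreground"])
    app = np.array([None, None, "A", "B", "A"], dtype=object)
    got = device_features(t, kind, app, np.full(5, np.nan), np.array([None] * 5), 0.0, 900.0)
    assert got["n_screen_on"] == 1 and got["n_screen_off"] == 1
    assert got["screen_dur_s"] == 300.0
    assert got["n_unique_apps"] == 2
    assert got["n_app_switches"] == 2
    # trailing unpaired on-event truncates at the window end
    got2 = device_features(
        np.array([800.0]), np.array(["screen_on"]), np.array([None], dtype=object),
        np.array([np.nan]), np.array([None]), 0.0, 900.0
    )
    assert got2["screen_dur_s"] == 100.0
    assert got2["n_screen_sessions"] == 1


def test_device_battery_features():
    t = np.array([0.0, 1800.0, 3600.0])
    kind = np.array(["battery"] * 3)
    pct = np.array([40.0, 70.0, 100.0])
    chg = np.array([True, True, True])
    got = device_features(t, kind, np.array([None] * 3, dtype=object), pct, chg, 0.0, 3600.0)
    assert got["charging_dur_s"] == 3600.0
    assert got["battery_pct_max"] == 100.0
    assert got["battery_drain_pct"] == -60.0


def test_wifi_union_semantics():
    assert wifi_feature(np.array([]))["n_unique_hotspots"] == 0
    got = wifi_feature(np.array([2, 2]), np.array(["a;b", "b;c"], dtype=object))
    assert got["n_unique_hotspots"] == 3
    dup = wifi_feature(np.array([2, 2]), np.array(["a;b", "a;b"], dtype=object))
    assert dup["n_unique_hotspots"] == 2
    nocount = wifi_feature(np.array([4, 2]))
    assert nocount["n_unique_hotspots"] == 4  # fallback: max per-scan count


# ---------------------------------------------------------------------------
# registry and windowed aggregation


def test_registry_has_exactly_70_unique_named_specs():
    assert len(FEATURE_REGISTRY) == 70
    assert len(set(FEATURE_NAMES)) == 70
    assert TIME_ENCODINGS == ["hour_of_day", "day_of_week"]
    streams = {"gps", "accel", "comm", "device", "wifi"}
    assert {s.stream for s in FEATURE_REGISTRY} <= streams
    fam = {s.family for s in FEATURE_REGISTRY}
    assert fam == {"location", "motion", "communication", "device", "environment"}


def test_window_features_returns_all_registered_names():
    day = 19_800 * DAY_S
    t = np.arange(day, day + 2 * HOUR_S, 300.0)
    streams = one_participant_streams(gps=gps_frame("pX", t, LAT0, LON0))
    p = ParticipantData("pX", 0, streams)
    row = window_features(p, day, day + HOUR_S)
    assert set(row) == set(FEATURE_NAMES)
    assert row["n_gps_fixes"] == 12
    assert row["radius_of_gyration"] == 0.0


def test_missingness_propagation():
    """No GPS -> location features missing (not zero); no comm events ->
    true zeros."""
    day = 19_800 * DAY_S
    t = np.arange(day, day + HOUR_S, 60.0)
    accel = pd.DataFrame(
        {"participant_id": "pX", "t": t, "x": 0.0, "y": 0.0, "z": 1.0}
    )
    streams = one_participant_streams(accel=accel)
    p = ParticipantData("pX", 0, streams)
    row = window_features(p, day, day + HOUR_S)
    assert np.isnan(row["radius_of_gyration"])
    assert np.isnan(row["location_entropy"])
    assert row["n_gps_fixes"] == 0
    assert row["n_calls_total"] == 0.0
    assert row["accel_mag_mean"] == pytest.approx(1.0)


def test_pooled_window_rog_dominates_epoch_rogs():
    """Pooling two anchor visits across epochs yields a radius at least as
    large as any single epoch's."""
    A = (LAT0, LON0)
    B = _offset(LAT0, LON0, 2000, 0)
    t1 = np.arange(0, 900, 60.0)
    t2 = np.arange(900, 1800, 60.0)
    lat = np.r_[np.full(len(t1), A[0]), np.full(len(t2), B[0])]
    lon = np.r_[np.full(len(t1), A[1]), np.full(len(t2), B[1])]
    r_pooled = radius_of_gyration(lat, lon)
    r1 = radius_of_gyration(lat[: len(t1)], lon[: len(t1)])
    r2 = radius_of_gyration(lat[len(t1):], lon[len(t1):])
    assert r_pooled >= max(r1, r2)
    assert r_pooled == pytest.approx(1000, rel=1e-3)


def test_instance_rows_have_registry_closure(small_cohort, small_events):
    from drinksense.features import build_instances

    _, streams, _ = small_cohort
    events, _ = small_events
    included = events[events["exclusion_reason"] == ""].head(12)
    inst = build_instances(streams, included, [WindowConfig(3, 1)])
    df = inst[WindowConfig(3, 1)]
    assert list(df.columns[:70]) == FEATURE_NAMES
    assert {"hour_of_day", "day_of_week", "label", "participant_id"} <= set(df.columns)
    assert df["hour_of_day"].between(0, 23).all()
    assert df["day_of_week"].between(0, 6).all()
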