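"""The 70 sensor features and their windowed computation.

Families and sources:

* ``location`` (30) — GPS: radius of gyration, location variance/entropy,
  circadian movement, travel distance and speed, significant-place visits
  and dwell, home-relative distances, coordinate statistics.
* ``motion`` (6) — accelerometer magnitude statistics computed two-stage:
  per-minute mean magnitudes first, then window statistics.
* ``communication`` (12) — call/SMS counts, durations, distinct contacts.
* ``device`` (18) — screen sessions, app use and switching, battery state.
* ``environment`` (4) — Wi-Fi hotspot counts.

Every feature is computed on a *pooled* time window ``[t0, t1)`` in local
seconds; the same routine serves both 15-minute epochs and w-hour analysis
windows (counts become window totals, mobility metrics are recomputed on
the pooled fixes).  Features whose source stream is silent in the window
are missing (NaN) — except communication/device/Wi-Fi counts, where the
absence of events is a true zero.

Distances are great-circle (haversine, Earth radius 6,371,000 m).
Significant places come from stay-point extraction (<=150 m, >=10 min)
followed by greedy 200 m centroid clustering over the whole study period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from .events import EpochSlice, WindowConfig
from .io import SensorStreams
from .timeutil import DAY_S, EPOCH_S, HOUR_S, day_of_week, hour_of_day

EARTH_RADIUS_M = 6_371_000.0

# significant-place parameters
STAY_DIST_M = 150.0
STAY_DWELL_S = 600.0
CLUSTER_MERGE_M = 200.0
PLACE_ASSIGN_M = 200.0
#: walking pace; faster fixes count as moving
SPEED_MOVING_MS = 1.4
#: night window that defines home
NIGHT_HOURS = (0, 6)
#: circadian period band (hours) and zero-energy floor
CM_BAND_H = (23.5, 24.5)
CM_FLOOR = 1e-12
ACCEL_ACTIVE_MAG = 1.5
APP_EVENT_CAP_S = 300.0


# ---------------------------------------------------------------------------
# geometry


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in meters (array-friendly)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def radius_of_gyration(lat, lon) -> float:
    """RMS great-circle distance of fixes from their (lat, lon) centroid."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0:
        return np.nan
    d = haversine_m(lat, lon, lat.mean(), lon.mean())
    return float(np.sqrt(np.mean(d**2)))


def location_variance(lat, lon) -> float:
    """Population variance of latitudes plus that of longitudes (deg^2)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size < 2:
        return np.nan
    return float(np.var(lat) + np.var(lon))


def location_entropy(dwell) -> float:
    """Shannon entropy (nats) of the dwell-time distribution over places."""
    dwell = np.asarray(dwell, dtype=float)
    total = dwell.sum()
    if dwell.size == 0 or total <= 0:
        return np.nan
    p = dwell[dwell > 0] / total
    return float(-(p * np.log(p)).sum())


def travel_distance(lat, lon) -> float:
    """Summed consecutive-fix great-circle distance in meters."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size < 2:
        return np.nan
    return float(haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]).sum())


def circadian_band_energy(
    t_s, values, band_h=CM_BAND_H, n_freq: int = 25
) -> float:
    """Integrated Lomb-Scargle power of a series over the ~24 h period band.

    Normalized periodogram (power relative to series variance) integrated
    over frequency; constant series have zero band energy.
    """
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2 or np.allclose(y, y[0]):
        return 0.0
    periods = np.linspace(band_h[0] * 3600, band_h[1] * 3600, n_freq)
    omega = 2 * np.pi / periods
    power = lombscargle(t, y - y.mean(), omega, normalize=True)
    freqs = 1.0 / periods
    order = np.argsort(freqs)
    return float(np.trapezoid(power[order], freqs[order]))


def circadian_movement(t_s, lat, lon, floor: float = CM_FLOOR) -> float:
    """log of summed latitude+longitude band energy near the 24 h period.

    Requires >= 24 fixes spanning >= 24 h; shorter series are missing.
    """
    t = np.asarray(t_s, dtype=float)
    if t.size < 24 or (t.max() - t.min()) < DAY_S - EPOCH_S:
        return np.nan
    energy = circadian_band_energy(t, lat) + circadian_band_energy(t, lon)
    return float(np.log(max(energy, floor)))


# ---------------------------------------------------------------------------
# significant places


def stay_points(t, lat, lon, dist_m=STAY_DIST_M, dwell_s=STAY_DWELL_S) -> pd.DataFrame:
    """Stay-point extraction: maximal runs of fixes within ``dist_m`` of the
    run's first fix lasting at least ``dwell_s``."""
    t = np.asarray(t, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    out = []
    i, n = 0, len(t)
    while i < n:
        j = i + 1
        while j < n and haversine_m(lat[i], lon[i], lat[j], lon[j]) <= dist_m:
            j += 1
        if j > i and t[j - 1] - t[i] >= dwell_s:
            out.append(
                (t[i], t[j - 1], lat[i:j].mean(), lon[i:j].mean(), t[j - 1] - t[i])
            )
            i = j
        else:
            i += 1
    return pd.DataFrame(out, columns=["t_start", "t_end", "lat", "lon", "dwell_s"])


def cluster_places(stays: pd.DataFrame, merge_m=CLUSTER_MERGE_M) -> pd.DataFrame:
    """Greedy centroid clustering of stay points into significant places.

    Stay points are folded, in dwell order, into the nearest existing place
    within ``merge_m`` (dwell-weighted centroid update) or start a new one.
    """
    cent_lat, cent_lon, dwell = [], [], []
    for s in stays.sort_values("dwell_s", ascending=False).itertuples():
        if cent_lat:
            d = haversine_m(np.array(cent_lat), np.array(cent_lon), s.lat, s.lon)
            k = int(np.argmin(d))
            if d[k] <= merge_m:
                w = dwell[k] + s.dwell_s
                cent_lat[k] = (cent_lat[k] * dwell[k] + s.lat * s.dwell_s) / w
                cent_lon[k] = (cent_lon[k] * dwell[k] + s.lon * s.dwell_s) / w
                dwell[k] = w
                continue
        cent_lat.append(s.lat)
        cent_lon.append(s.lon)
        dwell.append(s.dwell_s)
    places = pd.DataFrame({"lat": cent_lat, "lon": cent_lon, "dwell_s": dwell})
    places = places.sort_values("dwell_s", ascending=False).reset_index(drop=True)
    places["place_id"] = np.arange(len(places))
    return places


def significant_places(
    t_local, lat, lon, night_hours=NIGHT_HOURS
) -> tuple[pd.DataFrame, Optional[int]]:
    """Cluster a participant's full-study GPS into significant places and
    designate home as the place with maximal night-time (00:00-06:00) dwell.

    Returns ``(places sorted by total dwell, home place_id or None)``.
    """
    stays = stay_points(t_local, lat, lon)
    if stays.empty:
        return cluster_places(stays), None
    places = cluster_places(stays)
    # night dwell per place: assign each stay to its nearest place
    night = np.zeros(len(places))
    hod = (stays["t_start"].to_numpy() % DAY_S) / 3600
    is_night = (hod >= night_hours[0]) & (hod < night_hours[1])
    for s, nflag in zip(stays.itertuples(), is_night):
        if not nflag:
            continue
        d = haversine_m(places["lat"].to_numpy(), places["lon"].to_numpy(), s.lat, s.lon)
        k = int(np.argmin(d))
        if d[k] <= PLACE_ASSIGN_M:
            night[k] += s.dwell_s
    home = int(np.argmax(night)) if night.max() > 0 else None
    places["is_home"] = False
    if home is not None:
        places.loc[home, "is_home"] = True
    return places, home


# ---------------------------------------------------------------------------
# feature registry

@dataclass(frozen=True)
class FeatureSpec:
    name: str
    family: str
    stream: str
    units: str
    window_agg: str  # 'pooled' | 'sum' | 'mean' — semantics over a window


def _build_registry() -> list[FeatureSpec]:
    L, M, C, D, E = "location", "motion", "communication", "device", "environment"
    g, a, c, d, w = "gps", "accel", "comm", "device", "wifi"
    specs = [
        FeatureSpec("radius_of_gyration", L, g, "m", "pooled"),
        FeatureSpec("location_variance", L, g, "deg^2", "pooled"),
        FeatureSpec("location_entropy", L, g, "nats", "pooled"),
        FeatureSpec("normalized_location_entropy", L, g, "ratio", "pooled"),
        FeatureSpec("circadian_movement", L, g, "log-energy", "pooled"),
        FeatureSpec("travel_distance", L, g, "m", "pooled"),
        FeatureSpec("travel_speed_mean", L, g, "m/s", "pooled"),
        FeatureSpec("travel_speed_max", L, g, "m/s", "pooled"),
        FeatureSpec("n_places_visited", L, g, "count", "pooled"),
        FeatureSpec("n_places_passed", L, g, "count", "pooled"),
        FeatureSpec("n_place_transitions", L, g, "count", "pooled"),
        FeatureSpec("time_at_home_frac", L, g, "ratio", "pooled"),
        FeatureSpec("moving_time_frac", L, g, "ratio", "pooled"),
        FeatureSpec("stationary_time_frac", L, g, "ratio", "pooled"),
        FeatureSpec("wtsd_stationary_lat", L, g, "deg", "pooled"),
        FeatureSpec("wtsd_stationary_lon", L, g, "deg", "pooled"),
        FeatureSpec("displacement", L, g, "m", "pooled"),
        FeatureSpec("dwell_mean_min", L, g, "min", "pooled"),
        FeatureSpec("dwell_max_min", L, g, "min", "pooled"),
        FeatureSpec("n_gps_fixes", L, g, "count", "sum"),
        FeatureSpec("lat_mean", L, g, "deg", "pooled"),
        FeatureSpec("lon_mean", L, g, "deg", "pooled"),
        FeatureSpec("lat_std", L, g, "deg", "pooled"),
        FeatureSpec("lon_std", L, g, "deg", "pooled"),
    ]
    specs += [
        FeatureSpec(f"dwell_place_{k}_min", L, g, "min", "pooled") for k in range(1, 7)
    ]
    specs += [
        FeatureSpec("accel_mag_mean", M, a, "device", "pooled"),
        FeatureSpec("accel_mag_median", M, a, "device", "pooled"),
        FeatureSpec("accel_mag_std", M, a, "device", "pooled"),
        FeatureSpec("accel_mag_max", M, a, "device", "pooled"),
        FeatureSpec("accel_mag_min", M, a, "device", "pooled"),
        FeatureSpec("accel_active_frac", M, a, "ratio", "pooled"),
    ]
    specs += [
        FeatureSpec("n_calls_in", C, c, "count", "sum"),
        FeatureSpec("n_calls_out", C, c, "count", "sum"),
        FeatureSpec("n_calls_total", C, c, "count", "sum"),
        FeatureSpec("call_dur_in_s", C, c, "s", "sum"),
        FeatureSpec("call_dur_out_s", C, c, "s", "sum"),
        FeatureSpec("call_dur_total_s", C, c, "s", "sum"),
        FeatureSpec("call_dur_mean_s", C, c, "s", "pooled"),
        FeatureSpec("call_dur_max_s", C, c, "s", "pooled"),
        FeatureSpec("n_sms", C, c, "count", "sum"),
        FeatureSpec("n_contacts", C, c, "count", "pooled"),
        FeatureSpec("n_call_contacts", C, c, "count", "pooled"),
        FeatureSpec("n_sms_contacts", C, c, "count", "pooled"),
    ]
    specs += [
        FeatureSpec("n_screen_on", D, d, "count", "sum"),
        FeatureSpec("n_screen_off", D, d, "count", "sum"),
        FeatureSpec("n_screen_sessions", D, d, "count", "sum"),
        FeatureSpec("screen_dur_s", D, d, "s", "sum"),
        FeatureSpec("screen_session_mean_s", D, d, "s", "pooled"),
        FeatureSpec("screen_session_max_s", D, d, "s", "pooled"),
        FeatureSpec("n_app_events", D, d, "count", "sum"),
        FeatureSpec("n_unique_apps", D, d, "count", "pooled"),
        FeatureSpec("app_dur_s", D, d, "s", "sum"),
        FeatureSpec("n_app_switches", D, d, "count", "sum"),
        FeatureSpec("app_session_mean_s", D, d, "s", "pooled"),
        FeatureSpec("battery_pct_mean", D, d, "%", "pooled"),
        FeatureSpec("battery_pct_min", D, d, "%", "pooled"),
        FeatureSpec("battery_pct_max", D, d, "%", "pooled"),
        FeatureSpec("battery_pct_std", D, d, "%", "pooled"),
        FeatureSpec("battery_drain_pct", D, d, "%", "pooled"),
        FeatureSpec("charging_dur_s", D, d, "s", "sum"),
        FeatureSpec("full_charge_dur_s", D, d, "s", "sum"),
    ]
    specs += [
        FeatureSpec("n_unique_hotspots", E, w, "count", "pooled"),
        FeatureSpec("n_wifi_scans", E, w, "count", "sum"),
        FeatureSpec("hotspots_per_scan_mean", E, w, "count", "pooled"),
        FeatureSpec("hotspots_per_scan_max", E, w, "count", "pooled"),
    ]
    return specs


FEATURE_REGISTRY: list[FeatureSpec] = _build_registry()
FEATURE_NAMES: list[str] = [s.name for s in FEATURE_REGISTRY]
TIME_ENCODINGS = ["hour_of_day", "day_of_week"]

assert len(FEATURE_REGISTRY) == 70, "feature registry must hold exactly 70 specs"
assert len(set(FEATURE_NAMES)) == 70, "feature names must be unique"


def export_feature_spec(path) -> None:
    """Write the registry as ``feature_spec.json``."""
    payload = [
        {"name": s.name, "family": s.family, "stream": s.stream, "units": s.units,
         "window_agg": s.window_agg}
        for s in FEATURE_REGISTRY
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# per-participant pre-indexed streams


class ParticipantData:
    """One participant's streams as sorted numpy arrays in local time,
    plus their significant places — the fast substrate for windowing."""

    def __init__(self, pid: str, tz: int, streams: SensorStreams):
        self.pid = pid
        self.tz = tz

        def pull(name, cols):
            df = streams.stream(name)
            sub = df[df["participant_id"] == pid]
            t = sub["t"].to_numpy(dtype=float) + tz
            order = np.argsort(t, kind="mergesort")
            return (t[order],) + tuple(
                sub[c].to_numpy()[order] for c in cols
            )

        self.gps_t, self.gps_lat, self.gps_lon = pull("gps", ["lat", "lon"])
        t, x, y, z = pull("accel", ["x", "y", "z"])
        self.acc_t = t
        self.acc_mag = np.sqrt(
            x.astype(float) ** 2 + y.astype(float) ** 2 + z.astype(float) ** 2
        )
        self.comm_t, self.comm_kind, self.comm_dur, self.comm_contact = pull(
            "comm", ["kind", "duration", "contact_id"]
        )
        self.dev_t, self.dev_kind, self.dev_app, self.dev_pct, self.dev_chg = pull(
            "device", ["kind", "app_id", "battery_pct", "charging"]
        )
        wifi_cols = ["n_unique_hotspots"]
        has_ids = "hotspot_ids" in streams.wifi.columns
        if has_ids:
            wifi_cols.append("hotspot_ids")
        pulled = pull("wifi", wifi_cols)
        self.wifi_t, self.wifi_n = pulled[0], pulled[1].astype(float)
        self.wifi_ids = pulled[2] if has_ids else None

        self.places, self.home_id = significant_places(
            self.gps_t, self.gps_lat, self.gps_lon
        )

    def assign_places(self, lat, lon) -> np.ndarray:
        """Nearest significant place within the assignment radius, else -1."""
        if not len(self.places) or len(lat) == 0:
            return np.full(len(lat), -1)
        pl = self.places
        d = haversine_m(
            np.asarray(lat)[:, None],
            np.asarray(lon)[:, None],
            pl["lat"].to_numpy()[None, :],
            pl["lon"].to_numpy()[None, :],
        )
        k = np.argmin(d, axis=1)
        dk = d[np.arange(len(lat)), k]
        ids = pl["place_id"].to_numpy()[k]
        return np.where(dk <= PLACE_ASSIGN_M, ids, -1)


def participant_index(streams: SensorStreams) -> dict[str, ParticipantData]:
    out = {}
    for r in streams.participants.itertuples():
        out[r.participant_id] = ParticipantData(
            r.participant_id, int(r.tz_offset_s), streams
        )
    return out


# ---------------------------------------------------------------------------
# windowed feature computation


def _win(t, lo, hi):
    i, j = np.searchsorted(t, [lo, hi])
    return slice(i, j)


def accel_features(minute_means: np.ndarray) -> dict:
    """Window statistics over per-minute mean magnitudes."""
    if minute_means.size == 0:
        return {k: np.nan for k in (
            "accel_mag_mean", "accel_mag_median", "accel_mag_std",
            "accel_mag_max", "accel_mag_min", "accel_active_frac",
        )}
    return {
        "accel_mag_mean": float(minute_means.mean()),
        "accel_mag_median": float(np.median(minute_means)),
        "accel_mag_std": float(np.std(minute_means)),
        "accel_mag_max": float(minute_means.max()),
        "accel_mag_min": float(minute_means.min()),
        "accel_active_frac": float((minute_means > ACCEL_ACTIVE_MAG).mean()),
    }


def _location_features(p: ParticipantData, lo: float, hi: float) -> dict:
    out = {s.name: np.nan for s in FEATURE_REGISTRY if s.family == "location"}
    sl = _win(p.gps_t, lo, hi)
    t = p.gps_t[sl]
    lat = p.gps_lat[sl].astype(float)
    lon = p.gps_lon[sl].astype(float)
    out["n_gps_fixes"] = float(len(t))
    if len(t) == 0:
        return out

    out["radius_of_gyration"] = radius_of_gyration(lat, lon)
    out["location_variance"] = location_variance(lat, lon)
    out["lat_mean"] = float(lat.mean())
    out["lon_mean"] = float(lon.mean())
    out["lat_std"] = float(np.std(lat)) if len(t) >= 2 else np.nan
    out["lon_std"] = float(np.std(lon)) if len(t) >= 2 else np.nan
    out["travel_distance"] = travel_distance(lat, lon)
    out["displacement"] = (
        float(haversine_m(lat[0], lon[0], lat[-1], lon[-1])) if len(t) >= 2 else np.nan
    )

    stationary = np.ones(len(t), dtype=bool)
    if len(t) >= 2:
        step = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
        dt = np.diff(t)
        ok = dt > 0
        v = step[ok] / dt[ok]
        if v.size:
            out["travel_speed_mean"] = float(v.mean())
            out["travel_speed_max"] = float(v.max())
            out["moving_time_frac"] = float((v > SPEED_MOVING_MS).mean())
            out["stationary_time_frac"] = float((v <= SPEED_MOVING_MS).mean())
        vel = np.zeros(len(t))
        vel[:-1][ok] = v
        stationary = vel <= SPEED_MOVING_MS

    # dwell time attributed to each fix: interval to the next fix, last fix
    # gets the median interval; capped to avoid gap inflation
    if len(t) >= 2:
        iv = np.diff(t)
        med = float(np.median(iv))
        dwell_w = np.append(iv, med)
    else:
        dwell_w = np.array([EPOCH_S / 3.0])
    dwell_w = np.clip(dwell_w, 0, 1800.0)

    assigned = p.assign_places(lat, lon)
    known = assigned >= 0
    if known.any():
        ids = assigned[known]
        wts = dwell_w[known]
        uniq, inv = np.unique(ids, return_inverse=True)
        dwell_by_place = np.bincount(inv, weights=wts)
        out["n_places_passed"] = float(len(uniq))
        out["n_places_visited"] = float((dwell_by_place >= STAY_DWELL_S).sum())
        out["location_entropy"] = location_entropy(dwell_by_place)
        out["normalized_location_entropy"] = (
            out["location_entropy"] / np.log(len(uniq)) if len(uniq) > 1 else 0.0
        )
        for k in range(1, 7):
            pid_k = k - 1  # global dwell rank k
            m = uniq == pid_k
            out[f"dwell_place_{k}_min"] = (
                float(dwell_by_place[m][0] / 60) if m.any() else 0.0
            )
        if p.home_id is not None:
            m = uniq == p.home_id
            home_dwell = float(dwell_by_place[m][0]) if m.any() else 0.0
            out["time_at_home_frac"] = home_dwell / float(dwell_w.sum())
        # transitions between (compressed) consecutive known places
        run = ids[np.append(True, ids[1:] != ids[:-1])]
        out["n_place_transitions"] = float(len(run) - 1)
        # dwell runs
        run_bounds = np.flatnonzero(np.append(True, ids[1:] != ids[:-1]))
        run_dwell = np.add.reduceat(wts, run_bounds)
        out["dwell_mean_min"] = float(run_dwell.mean() / 60)
        out["dwell_max_min"] = float(run_dwell.max() / 60)
    else:
        out["n_places_passed"] = 0.0
        out["n_places_visited"] = 0.0
        out["n_place_transitions"] = 0.0

    # weighted stationary coordinate spread: dwell-weighted SD of the
    # latitudes/longitudes of fixes below walking pace
    if stationary.any():
        wts = dwell_w[stationary]
        if wts.sum() > 0:
            for key, coord in (("wtsd_stationary_lat", lat), ("wtsd_stationary_lon", lon)):
                c = coord[stationary]
                mu = np.average(c, weights=wts)
                out[key] = float(np.sqrt(np.average((c - mu) ** 2, weights=wts)))

    # a sub-day window cannot carry a 24 h rhythm: circadian movement is
    # computable only when the window itself spans at least a full day
    out["circadian_movement"] = circadian_movement(t, lat, lon)
    return out


def _motion_features(p: ParticipantData, lo: float, hi: float) -> dict:
    sl = _win(p.acc_t, lo, hi)
    t = p.acc_t[sl]
    if len(t) == 0:
        return accel_features(np.empty(0))
    minute = (t // 60).astype(np.int64)
    _, inv = np.unique(minute, return_inverse=True)
    sums = np.bincount(inv, weights=p.acc_mag[sl])
    counts = np.bincount(inv)
    return accel_features(sums / counts)


def comm_features(kind, duration, contact) -> dict:
    """Counts/sums over communication events; an empty window is all zeros."""
    kind = np.asarray(kind)
    duration = np.asarray(duration, dtype=float)
    contact = np.asarray(contact)
    is_in = kind == "call_in"
    is_out = kind == "call_out"
    is_call = is_in | is_out
    is_sms = kind == "sms"
    call_dur = duration[is_call]
    return {
        "n_calls_in": float(is_in.sum()),
        "n_calls_out": float(is_out.sum()),
        "n_calls_total": float(is_call.sum()),
        "call_dur_in_s": float(duration[is_in].sum()),
        "call_dur_out_s": float(duration[is_out].sum()),
        "call_dur_total_s": float(call_dur.sum()),
        "call_dur_mean_s": float(call_dur.mean()) if call_dur.size else 0.0,
        "call_dur_max_s": float(call_dur.max()) if call_dur.size else 0.0,
        "n_sms": float(is_sms.sum()),
        "n_contacts": float(len(np.unique(contact))) if contact.size else 0.0,
        "n_call_contacts": float(len(np.unique(contact[is_call]))),
        "n_sms_contacts": float(len(np.unique(contact[is_sms]))),
    }


def device_features(t, kind, app, pct, charging, lo, hi) -> dict:
    """Screen sessions (paired on/off, truncated at window edges), app use,
    and battery state over a window."""
    t = np.asarray(t, dtype=float)
    kind = np.asarray(kind)
    out = {}
    on_t = t[kind == "screen_on"]
    off_t = t[kind == "screen_off"]
    out["n_screen_on"] = float(len(on_t))
    out["n_screen_off"] = float(len(off_t))
    # pair each on with the next off; leading off closes a session begun
    # before the window, trailing on truncates at the window end
    sessions = []
    if len(off_t) and (not len(on_t) or off_t[0] < on_t[0]):
        sessions.append(off_t[0] - lo)
        off_rest = off_t[1:]
    else:
        off_rest = off_t
    j = 0
    for s in on_t:
        while j < len(off_rest) and off_rest[j] < s:
            j += 1
        if j < len(off_rest):
            sessions.append(off_rest[j] - s)
            j += 1
        else:
            sessions.append(hi - s)
    sess = np.array(sessions, dtype=float)
    out["n_screen_sessions"] = float(len(sess))
    out["screen_dur_s"] = float(sess.sum()) if sess.size else 0.0
    out["screen_session_mean_s"] = float(sess.mean()) if sess.size else 0.0
    out["screen_session_max_s"] = float(sess.max()) if sess.size else 0.0

    is_app = kind == "app_foreground"
    app_t = t[is_app]
    apps = np.asarray(app)[is_app]
    out["n_app_events"] = float(len(app_t))
    out["n_unique_apps"] = float(len(np.unique(apps))) if len(apps) else 0.0
    if len(app_t):
        nxt = np.append(np.diff(app_t), APP_EVENT_CAP_S)
        dur = np.minimum(nxt, APP_EVENT_CAP_S)
        out["app_dur_s"] = float(dur.sum())
        out["app_session_mean_s"] = float(dur.mean())
        out["n_app_switches"] = float((apps[1:] != apps[:-1]).sum())
    else:
        out["app_dur_s"] = 0.0
        out["app_session_mean_s"] = 0.0
        out["n_app_switches"] = 0.0

    is_bat = kind == "battery"
    bt = t[is_bat]
    bpct = np.asarray(pct, dtype=float)[is_bat]
    bchg = np.asarray(charging)[is_bat]
    if len(bt):
        out["battery_pct_mean"] = float(bpct.mean())
        out["battery_pct_min"] = float(bpct.min())
        out["battery_pct_max"] = float(bpct.max())
        out["battery_pct_std"] = float(np.std(bpct))
        out["battery_drain_pct"] = float(bpct[0] - bpct[-1])
        iv = np.minimum(np.append(np.diff(bt), hi - bt[-1]), 2 * 1800.0)
        chg = np.array([bool(c) for c in bchg])
        out["charging_dur_s"] = float(iv[chg].sum())
        out["full_charge_dur_s"] = float(iv[chg & (bpct >= 99.5)].sum())
    else:
        for k in ("battery_pct_mean", "battery_pct_min", "battery_pct_max",
                  "battery_pct_std", "battery_drain_pct"):
            out[k] = np.nan
        out["charging_dur_s"] = 0.0
        out["full_charge_dur_s"] = 0.0
    return out


def wifi_feature(n_per_scan, ids_per_scan=None) -> dict:
    """Unique-hotspot count over a window: union of scan identifier sets
    when identifiers are available, else the max per-scan count."""
    n = np.asarray(n_per_scan, dtype=float)
    if n.size == 0:
        return {
            "n_unique_hotspots": 0.0,
            "n_wifi_scans": 0.0,
            "hotspots_per_scan_mean": 0.0,
            "hotspots_per_scan_max": 0.0,
        }
    if ids_per_scan is not None:
        union = set()
        for s in ids_per_scan:
            if isinstance(s, str) and s:
                union.update(s.split(";"))
        n_unique = float(len(union))
    else:
        n_unique = float(n.max())
    return {
        "n_unique_hotspots": n_unique,
        "n_wifi_scans": float(n.size),
        "hotspots_per_scan_mean": float(n.mean()),
        "hotspots_per_scan_max": float(n.max()),
    }


def window_features(p: ParticipantData, lo: float, hi: float) -> dict:
    """All 70 features over the pooled local-time window ``[lo, hi)``."""
    out = {}
    out.update(_location_features(p, lo, hi))
    out.update(_motion_features(p, lo, hi))
    sl = _win(p.comm_t, lo, hi)
    out.update(comm_features(p.comm_kind[sl], p.comm_dur[sl], p.comm_contact[sl]))
    sl = _win(p.dev_t, lo, hi)
    out.update(
        device_features(
            p.dev_t[sl], p.dev_kind[sl], p.dev_app[sl], p.dev_pct[sl], p.dev_chg[sl],
            lo, hi,
        )
    )
    sl = _win(p.wifi_t, lo, hi)
    out.update(
        wifi_feature(
            p.wifi_n[sl], p.wifi_ids[sl] if p.wifi_ids is not None else None
        )
    )
    return out


def epoch_feature_rows(epochs: EpochSlice, p: ParticipantData) -> pd.DataFrame:
    """Per-epoch feature rows (the 15-minute granularity of the registry)."""
    rows = []
    for start, miss in zip(epochs.starts_local_s, epochs.missing):
        f = window_features(p, float(start), float(start + EPOCH_S))
        f["participant_id"] = p.pid
        f["epoch_start_local_s"] = int(start)
        f["hour_of_day"] = int(hour_of_day(start))
        f["day_of_week"] = int(day_of_week(start))
        f["epoch_missing"] = bool(miss)
        rows.append(f)
    return pd.DataFrame(rows)


def aggregate_over_window(
    epochs: EpochSlice, p: ParticipantData, cfg: WindowConfig
) -> Optional[dict]:
    """One model-ready instance from an analysis-window epoch slice.

    Features are recomputed on the pooled window span; time encodings are
    the hour of day at prediction time (window end = onset - d) and the day
    of week of the event onset.  A slice with no data at all yields None
    (instance dropped).
    """
    if epochs.missing.all():
        return None
    lo, hi = epochs.span
    row = window_features(p, float(lo), float(hi))
    row["hour_of_day"] = int(hour_of_day(hi))
    row["day_of_week"] = int(day_of_week(epochs.onset_snap_s))
    row["participant_id"] = p.pid
    return row


def build_instances(
    streams: SensorStreams,
    events: pd.DataFrame,
    cfgs: list[WindowConfig],
    pindex: Optional[dict] = None,
) -> dict[WindowConfig, pd.DataFrame]:
    """Instance matrices for every window configuration.

    ``events`` should already be inclusion-filtered; rows whose analysis
    window holds no data are dropped (logged via the returned frame sizes).
    """
    from .events import epochize, extract_window  # local to avoid cycle

    pindex = pindex or participant_index(streams)
    all_times = {
        pid: np.sort(
            np.concatenate([p.gps_t, p.acc_t, p.comm_t, p.dev_t, p.wifi_t])
        )
        for pid, p in pindex.items()
    }
    out: dict[WindowConfig, list] = {cfg: [] for cfg in cfgs}
    for event in events.itertuples():
        p = pindex[event.participant_id]
        ep = epochize(event, times=all_times[event.participant_id])
        for cfg in cfgs:
            sl = extract_window(ep, cfg)
            row = aggregate_over_window(sl, p, cfg)
            if row is None:
                continue
            row["label"] = event.label
            row["day_class"] = event.day_class
            row["date"] = event.date
            out[cfg].append(row)
    cols = FEATURE_NAMES + TIME_ENCODINGS + ["participant_id", "date", "label", "day_class"]
    return {
        cfg: pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
        for cfg, rows in out.items()
    }
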