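"""Seeded synthetic cohort generator.

Emulates a 75-participant, 14-week mobile-sensing study of young-adult
drinking: twice-weekly self-reports of drinking occasions (non-drinking /
low-risk / binge) plus continuous phone sensor streams (GPS, accelerometer,
call/SMS logs, screen/app/battery events, Wi-Fi scans).

The generative model, in brief:

* Each participant-day independently produces at most one reported event.
  The per-day report probability and the class-conditional day-of-week
  distributions are chosen so that (i) the expected report rate is two per
  week times a compliance factor and (ii) the day-of-week distribution of
  simulated binge events equals the configured (observed-frequency) vector
  exactly — a property the chi-square calibration tests rely on.
* A latent per-day "social outing" state mediates both the drinking class
  and the sensor streams: in the hours before a drinking onset the
  trajectory tours bar/venue anchor places (raising the radius of gyration
  and the number of places visited) while accelerometer magnitude and
  communication volume drop.  Effect sizes are configurable; at zero effect
  the streams carry no class information beyond chance, which downstream
  null-calibration tests exploit.
* Onset clock times are drawn from a configurable hourly distribution; the
  ``hour`` and ``day_of_week`` effect sizes interpolate between
  uninformative references (uniform over 18:00-24:00 / uniform over days)
  and the calibrated tables.

Everything is driven by one integer seed through ``numpy.random.Generator``
spawning, so a fixed config reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io import SensorStreams
from .timeutil import DAY_S, HOUR_S

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "TABLE_BDE_DAY_OF_WEEK",
    "TABLE_BDE_ONSET_HOUR",
    "table_calibrated_config",
    "sample_events",
    "simulate_cohort",
    "inject_missingness",
]

# Reference study scale: reported event counts before and after the
# sensor-coverage exclusions, for 75 participants over 14 weeks.
STUDY_COUNTS_PRE = {"N": 729, "D": 236, "BDE": 203}
STUDY_COUNTS_POST = {"N": 489, "D": 143, "BDE": 122}
STUDY_N_PARTICIPANTS = 75

# Observed binge-event frequencies used for calibration:
# counts by day of week (Monday..Sunday) and by onset hour bin (n=122).
TABLE_BDE_DAY_OF_WEEK = np.array([2, 0, 5, 7, 36, 52, 20], dtype=float)
TABLE_BDE_ONSET_HOUR = np.array(
    [3, 0, 0, 0, 1, 0, 1, 4, 1, 3, 6, 3, 5, 2, 6, 9, 7, 15, 11, 12, 11, 8, 10, 4],
    dtype=float,
)

#: day index (days since 1970-01-01, local) of the first study day; a Monday.
STUDY_DAY0 = 19723

_SLOT_S = 300  # trajectory/accelerometer slot
_SLOTS_PER_DAY = DAY_S // _SLOT_S


def _norm(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / v.sum()


def _evening_uniform() -> np.ndarray:
    v = np.zeros(24)
    v[18:24] = 1 / 6
    return v


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the reference study's scale: 75 participants
    observed for 14 weeks, ~71% women, a pre-exclusion event mix of
    729:236:203 (non-drinking : low-risk : binge) over 1168 expected
    reports, binge day-of-week and onset-hour distributions equal to the
    observed frequency tables, and missingness heavy enough to discard
    roughly a third of events downstream (participants disabling GPS being
    the dominant cause).
    """

    n_participants: int = 75
    n_weeks: int = 14
    seed: int = 7
    frac_female: float = 0.71
    tz_offset_s: int = -5 * HOUR_S

    # P(class) for a reported event, N / D / BDE
    base_rates: dict = field(
        default_factory=lambda: {"N": 729 / 1168, "D": 236 / 1168, "BDE": 203 / 1168}
    )
    #: compliance: expected reports per participant-week = 2 * report_rate
    report_rate: float = 1168 / (75 * 14 * 2)

    # class-conditional day-of-week distributions (Mon..Sun), fully informed
    dow_dist: dict = field(
        default_factory=lambda: {
            "N": np.full(7, 1 / 7),
            "D": _norm([0.05, 0.05, 0.10, 0.15, 0.25, 0.25, 0.15]),
            "BDE": _norm(TABLE_BDE_DAY_OF_WEEK),
        }
    )
    # Class-conditional onset-hour distributions (24 bins), fully informed.
    # The frequency table constrains binge events only; low-risk occasions
    # get a flatter evening-weighted mixture.
    onset_hour_dist: dict = field(
        default_factory=lambda: {
            "D": 0.5 * _norm(TABLE_BDE_ONSET_HOUR) + 0.5 * _evening_uniform(),
            "BDE": _norm(TABLE_BDE_ONSET_HOUR),
        }
    )

    #: latent-state coupling strengths in [0, 1]; all zero => streams carry
    #: no class signal (the null generator)
    effect_sizes: dict = field(
        default_factory=lambda: {
            "hour": 1.0,
            "day_of_week": 1.0,
            "radius_of_gyration": 1.0,
            "n_places": 1.0,
            "accel": 1.0,
            "communication": 1.0,
        }
    )

    #: class-independent baseline probability of an evening outing
    outing_p_n: float = 0.2
    #: range of the per-event pre-onset mobility horizon (hours)
    preonset_hours_range: tuple = (4.0, 10.0)

    missingness: dict = field(
        default_factory=lambda: {
            "gps_day_off_p": 0.28,  # participant disabled GPS for the day
            "blackout_day_p": 0.06,  # phone dead: every stream silent
            "blackout_hours": (2.0, 8.0),
            "short_gaps_per_day": 2.0,  # per stream, a few-minute dropout
            "short_gap_minutes": (5.0, 15.0),
        }
    )

    gps_period_s: int = _SLOT_S
    accel_period_s: int = _SLOT_S
    wifi_period_s: int = 900
    battery_period_s: int = 1800

    def __post_init__(self):
        if self.n_participants <= 0 or self.n_weeks <= 0:
            raise ValueError("n_participants and n_weeks must be positive")
        rates = np.array([self.base_rates[c] for c in ("N", "D", "BDE")])
        if np.any(rates < 0) or not np.isclose(rates.sum(), 1.0):
            raise ValueError("base_rates must be a probability vector over N/D/BDE")
        for c, v in self.dow_dist.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (7,) or not np.isclose(v.sum(), 1.0):
                raise ValueError(f"dow_dist[{c}] must be a length-7 probability vector")
        for c, v in self.onset_hour_dist.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (24,) or not np.isclose(v.sum(), 1.0):
                raise ValueError(f"onset_hour_dist[{c}] must have 24 bins summing to 1")
        if not 0.0 <= self.report_rate <= 1.0:
            raise ValueError("report_rate must lie in [0, 1]")
        for k, v in self.effect_sizes.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"effect_sizes[{k}] must lie in [0, 1]")

    @property
    def n_days(self) -> int:
        return self.n_weeks * 7

    def with_effects(self, value: float) -> "CohortConfig":
        """Copy with every effect size set to ``value`` (0 = null cohort)."""
        return replace(self, effect_sizes={k: value for k in self.effect_sizes})


def table_calibrated_config(**overrides) -> CohortConfig:
    """Config whose binge day-of-week and onset-hour distributions equal the
    normalized observed frequency tables (they are also the defaults)."""
    return CohortConfig(**overrides)


@dataclass
class GroundTruth:
    """What the generator actually did: per-day classes, latent states and
    onsets, anchor places, and injected gaps — for parameter-recovery tests."""

    events: pd.DataFrame  # one row per reported event
    anchors: pd.DataFrame  # participant anchor places with kinds
    gaps: pd.DataFrame  # injected missing spans
    config: CohortConfig


# ---------------------------------------------------------------------------
# event-level sampling


def _effective_dow(cfg: CohortConfig, cls: str) -> np.ndarray:
    e = cfg.effect_sizes["day_of_week"]
    return (1 - e) / 7 + e * np.asarray(cfg.dow_dist[cls], dtype=float)


def _effective_onset_hour(cfg: CohortConfig, cls: str) -> np.ndarray:
    # uninformative reference: uniform over 18:00-24:00, mirroring the
    # pseudo-onset convention for non-drinking days
    ref = np.zeros(24)
    ref[18:24] = 1 / 6
    e = cfg.effect_sizes["hour"]
    return (1 - e) * ref + e * np.asarray(cfg.onset_hour_dist[cls], dtype=float)


def make_participants(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_participants
    sex = np.where(rng.random(n) < cfg.frac_female, "female", "male")
    return pd.DataFrame(
        {
            "participant_id": [f"p{i:03d}" for i in range(n)],
            "sex": sex,
            "enrolled_days": cfg.n_days,
            "tz_offset_s": cfg.tz_offset_s,
        }
    )


def sample_events(
    cfg: CohortConfig, rng: np.random.Generator, participants: pd.DataFrame
) -> pd.DataFrame:
    """Draw the per-day report/class/onset table (no sensor streams).

    Each participant-day reports an event of class ``c`` with probability
    ``2 * report_rate * P(c) * P(dow | c)`` so that, conditional on class,
    the day-of-week distribution is exactly the configured vector.
    """
    n_p, n_d = len(participants), cfg.n_days
    classes = ("N", "D", "BDE")
    dows = (np.arange(n_d) % 7).astype(int)  # study starts on a Monday

    # per-day class probabilities, shape (7, 3)
    p_by_dow = np.zeros((7, 3))
    for j, cls in enumerate(classes):
        p_by_dow[:, j] = 2 * cfg.report_rate * cfg.base_rates[cls] * _effective_dow(cfg, cls)
    if p_by_dow.sum(axis=1).max() > 1.0:
        raise ValueError("report_rate too high for the configured day distributions")
    cum = np.cumsum(p_by_dow, axis=1)  # (7, 3)

    u = rng.random((n_p, n_d))
    day_cum = cum[dows]  # (n_d, 3)
    # class index per cell; 3 = no event
    cls_code = (u[:, :, None] >= day_cum[None, :, :]).sum(axis=2)
    pi, di = np.nonzero(cls_code < 3)
    cls_arr = np.array(classes)[cls_code[pi, di]]

    ev = pd.DataFrame(
        {
            "participant_id": participants["participant_id"].to_numpy()[pi],
            "sex": participants["sex"].to_numpy()[pi],
            "day_index": di,
            "day_of_week": dows[di],
            "label": cls_arr,
        }
    )

    # onset clock time for drinking events
    onset_s = np.full(len(ev), np.nan)
    n_drinks = np.zeros(len(ev), dtype=int)
    for cls in ("D", "BDE"):
        m = (ev["label"] == cls).to_numpy()
        if not m.any():
            continue
        hours = rng.choice(24, size=m.sum(), p=_effective_onset_hour(cfg, cls))
        minutes = rng.integers(0, 60, size=m.sum())
        onset_s[m] = hours * 3600 + minutes * 60
        thr = np.where(ev.loc[m, "sex"].to_numpy() == "female", 4, 5)
        if cls == "D":
            n_drinks[m] = 1 + (rng.random(m.sum()) * (thr - 1)).astype(int)
        else:
            n_drinks[m] = thr + rng.poisson(1.5, size=m.sum())
    ev["onset_second_of_day"] = onset_s
    ev["n_drinks"] = n_drinks

    drinking = ev["label"].isin(["D", "BDE"]).to_numpy()
    e_out = max(cfg.effect_sizes["radius_of_gyration"], cfg.effect_sizes["n_places"])
    # At full effect 85% of evening drinking occasions are preceded by a
    # venue outing, but daytime onsets rarely are — those events are
    # detectable only through their onset clock time.  At zero effect the
    # outing rate is class-independent.
    evening = np.nan_to_num(onset_s) >= 16 * 3600
    p_drink = np.where(evening, 0.85, 0.10)
    p_out = np.where(
        drinking, cfg.outing_p_n + (p_drink - cfg.outing_p_n) * e_out, cfg.outing_p_n
    )
    ev["outing"] = rng.random(len(ev)) < p_out
    # Latent outing time.  On drinking days the outing leads into the onset
    # only with probability e_out (the planted temporal coupling); otherwise
    # — and always on non-drinking days — it falls at an independent evening
    # hour.  At zero effect the outing process is therefore identically
    # distributed across classes and carries no signal.
    aligned = drinking & ev["outing"].to_numpy() & (rng.random(len(ev)) < e_out)
    out_s = np.where(aligned, onset_s, rng.integers(18 * 3600, 24 * 3600, size=len(ev)).astype(float))
    ev["outing_aligned"] = aligned
    ev["outing_second_of_day"] = np.where(ev["outing"], out_s, np.nan)
    # per-event going-out horizon: how long before the onset mobility and
    # behavior shift (afternoon errands, pre-gaming, venue hopping)
    ev["preonset_h"] = rng.uniform(*cfg.preonset_hours_range, size=len(ev))

    # absolute local onset (seconds since epoch, local clock)
    day_local = (STUDY_DAY0 + ev["day_index"].to_numpy()) * DAY_S
    ev["onset_local_s"] = day_local + ev["onset_second_of_day"]
    ev["end_local_s"] = ev["onset_local_s"] + 3600 + 1800 * ev["n_drinks"]
    ev["date"] = [
        pd.Timestamp("1970-01-01") + pd.Timedelta(days=int(STUDY_DAY0 + d))
        for d in ev["day_index"]
    ]
    ev["date"] = ev["date"].dt.date.astype(str)
    return ev.reset_index(drop=True)


def events_to_ema(events: pd.DataFrame) -> pd.DataFrame:
    """Render the ground-truth event table as the self-report stream."""
    drank = events["label"].isin(["D", "BDE"]).to_numpy()

    def clock(sec):
        sec = np.where(np.isnan(sec), 0, sec).astype(int)
        return [f"{s // 3600 % 24:02d}:{s % 3600 // 60:02d}" for s in sec]

    start = events["onset_second_of_day"].to_numpy()
    end = start + 3600 + 1800 * events["n_drinks"].to_numpy()
    return pd.DataFrame(
        {
            "participant_id": events["participant_id"],
            "report_date": events["date"],
            "drank": drank,
            "n_drinks": np.where(drank, events["n_drinks"], 0),
            "start_time": np.where(drank, clock(start), ""),
            "end_time": np.where(drank, clock(end), ""),
            "end_next_day": np.where(drank, end >= DAY_S, False),
        }
    )


# ---------------------------------------------------------------------------
# trajectory and stream synthesis

_WIFI_MEAN = {"home": 5.0, "work": 9.0, "venue": 10.0, "event_venue": 10.0}
_POOL = 30  # hotspot identifiers per anchor

#: shared city nightlife districts: drinking-event venues gravitate here, so
#: absolute coordinates carry class signal (the basis of the location map and
#: the coordinate-rounding privacy experiment)
_DISTRICTS = ((40.47, -80.04), (40.41, -79.96))


def _make_anchors(cfg: CohortConfig, rng: np.random.Generator, pid: str) -> pd.DataFrame:
    """Home, work, and 2-5 habitual nearby venues per participant.

    Homes cluster tightly around the city center so that the nightlife
    districts (offset ~0.04 deg) sit outside the residential cloud and
    absolute coordinates carry population-level information.
    """
    lat0 = 40.44 + rng.normal(0, 0.02)
    lon0 = -80.00 + rng.normal(0, 0.02)
    rows = [("home", lat0, lon0), ("work", lat0 + rng.normal(0, 0.015), lon0 + rng.normal(0, 0.015))]
    for _ in range(int(rng.integers(2, 6))):
        rows.append(("venue", lat0 + rng.normal(0, 0.010), lon0 + rng.normal(0, 0.010)))
    return pd.DataFrame(
        {
            "participant_id": pid,
            "anchor_idx": np.arange(len(rows)),
            "kind": [k for k, *_ in rows],
            "lat": [a for _, a, _ in rows],
            "lon": [b for _, _, b in rows],
        }
    )


def _day_schedule(
    cfg,
    rng,
    anchors: pd.DataFrame,
    n_days: int,
    events: pd.DataFrame,
):
    """Anchor index per 5-minute slot over the whole study for one person.

    Outing evenings tour one or two venues before the (latent) onset and
    stay at the last one; the drinking class acts purely through the radial
    distance of the toured venues (the planted radius-of-gyration effect),
    scaled by ``effect_sizes['radius_of_gyration']``.  Event-specific
    venues are appended to the anchor table, so tour size and venue novelty
    are class-independent.

    Returns ``(schedule, extended anchors)``.
    """
    n_slots = n_days * _SLOTS_PER_DAY
    sched = np.zeros(n_slots, dtype=np.int32)  # default: home (= anchor 0)
    kinds = anchors["kind"].to_numpy()
    venue_idx = np.flatnonzero(kinds == "venue")
    work_idx = int(np.flatnonzero(kinds == "work")[0])
    home_lat = float(anchors.loc[0, "lat"])
    home_lon = float(anchors.loc[0, "lon"])
    new_rows = []

    def put(lo_s, hi_s, anchor):
        lo = max(0, int(lo_s // _SLOT_S))
        hi = min(n_slots, int(np.ceil(hi_s / _SLOT_S)))
        if hi > lo:
            sched[lo:hi] = anchor

    for d in range(n_days):
        base = d * DAY_S
        dow = d % 7
        if dow < 5:
            put(base + 9 * HOUR_S, base + 17 * HOUR_S, work_idx)
        elif rng.random() < 0.5 and len(venue_idx):
            # weekend errand, class-independent mobility noise
            v = int(rng.choice(venue_idx))
            t0 = base + rng.uniform(12, 16) * HOUR_S
            put(t0, t0 + rng.uniform(1, 2) * HOUR_S, v)

    e_r = cfg.effect_sizes["radius_of_gyration"]
    for ev in events.itertuples():
        if not ev.outing or np.isnan(ev.outing_second_of_day):
            continue
        onset = ev.day_index * DAY_S + ev.outing_second_of_day
        # venue distance multiplier is the planted class effect; ranges
        # overlap so no single mobility feature separates the classes alone
        if ev.label == "BDE":
            scale = 1.0 + e_r * rng.uniform(0.8, 2.4)
        elif ev.label == "D":
            scale = 1.0 + e_r * rng.uniform(0.2, 1.4)
        else:
            scale = 1.0
        # tour size is class-independent; the excursion venue (scaled
        # distance, possibly in a nightlife district) sits at a random tour
        # position so no single endpoint feature can summarize it
        k = 2 + int(rng.random() < 0.5) if ev.outing_aligned else 1 + int(rng.random() < 0.5)
        # a district evening spends the whole excursion in the nightlife
        # district; otherwise stops scatter around home at scaled distances
        p_district = {"BDE": 0.5, "D": 0.12, "N": 0.05}[ev.label] * e_r
        in_district = rng.random() < p_district
        dlat, dlon = _DISTRICTS[int(rng.integers(len(_DISTRICTS)))]
        tour = []
        for j in range(k):
            if in_district:
                vlat = dlat + rng.normal(0, 0.004)
                vlon = dlon + rng.normal(0, 0.004)
            else:
                r = rng.uniform(0.008, 0.018) * scale
                ang = rng.uniform(0, 2 * np.pi)
                vlat = home_lat + r * np.sin(ang)
                vlon = home_lon + r * np.cos(ang)
            tour.append((vlat, vlon))
        # head out to the farthest stop first, then drift back toward home
        tour.sort(
            key=lambda p: -np.hypot(p[0] - home_lat, p[1] - home_lon)
        )
        idx0 = len(anchors) + len(new_rows)
        for vlat, vlon in tour:
            new_rows.append(("event_venue", vlat, vlon))
        tour = list(range(idx0, idx0 + len(tour)))
        # the excursion ends ~1.5 h before the onset; the occasion itself
        # happens at the settle venue or back home (house party), a choice
        # independent of the drinking class
        pre = ev.preonset_h * HOUR_S
        settle = onset - 1.5 * HOUR_S
        bounds = np.linspace(onset - pre, settle, len(tour) + 1)
        for v, lo, hi in zip(tour, bounds[:-1], bounds[1:]):
            put(lo, hi, v)
        if ev.outing_aligned:
            stay_end = ev.end_local_s - STUDY_DAY0 * DAY_S
        else:
            stay_end = onset + 1.5 * HOUR_S
        # district evenings stay downtown; otherwise most occasions settle
        # back home (house party), keeping the endpoint uninformative about
        # roaming distance
        if in_district:
            stay_at = tour[-1]
        else:
            stay_at = 0 if rng.random() < 0.7 else tour[-1]  # 0 = home
        put(settle, stay_end, stay_at)
    if new_rows:
        ext = pd.DataFrame(
            {
                "participant_id": anchors["participant_id"].iloc[0],
                "anchor_idx": np.arange(len(anchors), len(anchors) + len(new_rows)),
                "kind": [k for k, *_ in new_rows],
                "lat": [a for _, a, _ in new_rows],
                "lon": [b for _, _, b in new_rows],
            }
        )
        anchors = pd.concat([anchors, ext], ignore_index=True)
    return sched, anchors


def _synth_participant(cfg, rng, pid, anchors, events):
    """All sensor streams for one participant (no missingness yet)."""
    n_days = cfg.n_days
    n_slots = n_days * _SLOTS_PER_DAY
    tz = cfg.tz_offset_s
    day0_local = STUDY_DAY0 * DAY_S
    slot_local = day0_local + np.arange(n_slots, dtype=np.int64) * _SLOT_S

    sched, anchors = _day_schedule(cfg, rng, anchors, n_days, events)
    alat = anchors["lat"].to_numpy()[sched].copy()
    alon = anchors["lon"].to_numpy()[sched].copy()
    moving = np.zeros(n_slots, dtype=bool)
    # travel between anchors is interpolated at roughly constant urban
    # speed, so instantaneous GPS speed saturates instead of encoding the
    # hop distance; longer trips take more slots
    for i in np.flatnonzero(sched[1:] != sched[:-1]) + 1:
        d_m = 1.11e5 * float(
            np.hypot(alat[i] - alat[i - 1], alon[i] - alon[i - 1])
        )
        travel_ms = rng.uniform(5.0, 25.0)  # walk / bus / car mix per trip
        n_tr = min(12, max(1, int(d_m / (travel_ms * _SLOT_S))))
        hi = min(n_slots, i + n_tr)
        frac = (np.arange(i, hi) - (i - 1)) / (hi - (i - 1))
        alat[i:hi] = alat[i - 1] + frac * (alat[hi - 1] - alat[i - 1])
        alon[i:hi] = alon[i - 1] + frac * (alon[hi - 1] - alon[i - 1])
        moving[i:hi] = True
    lat = alat + rng.normal(0, 2e-4, n_slots)
    lon = alon + rng.normal(0, 2e-4, n_slots)
    # sporadic multipath glitches: km-scale position errors on ~0.4% of fixes
    glitch = rng.random(n_slots) < 0.004
    lat[glitch] += rng.normal(0, 0.02, glitch.sum())
    lon[glitch] += rng.normal(0, 0.02, glitch.sum())

    t_gps = slot_local - tz + rng.integers(0, 60, n_slots)
    gps = pd.DataFrame(
        {
            "participant_id": pid,
            "t": t_gps,
            "lat": lat,
            "lon": lon,
            "accuracy": np.round(rng.uniform(5, 30, n_slots), 1),
        }
    )

    # --- latent pre-onset state mask (per slot) ------------------------------
    damp_accel = np.ones(n_slots)
    damp_comm = np.ones(n_slots)
    e_a = cfg.effect_sizes["accel"]
    e_c = cfg.effect_sizes["communication"]
    for ev in events.itertuples():
        # the latent outing state mediates every sensor effect: drinking
        # days without an outing leave no trace in the streams, so the
        # onset-hour distribution carries their only signal; damping is
        # itself probabilistic so no channel is a deterministic marker
        if not getattr(ev, "outing_aligned", False) or np.isnan(ev.onset_second_of_day):
            continue
        if rng.random() > 0.6:
            continue
        onset = ev.day_index * DAY_S + ev.onset_second_of_day
        lo = max(0, int((onset - ev.preonset_h * HOUR_S) // _SLOT_S))
        hi = min(n_slots, int((onset - 1.5 * HOUR_S) // _SLOT_S) + 1)
        damp_accel[lo:hi] = 1 - 0.22 * e_a
        damp_comm[lo:hi] = 1 - 0.40 * e_c

    # --- accelerometer -------------------------------------------------------
    # per-day circadian jitter (wake time, activity level) keeps the
    # nuisance streams from acting as deterministic clocks
    second = slot_local % DAY_S
    wake_s = np.repeat(rng.uniform(6, 9, n_days) * HOUR_S, _SLOTS_PER_DAY)
    day_mult = np.repeat(rng.lognormal(0, 0.25, n_days), _SLOTS_PER_DAY)
    awake = second >= wake_s
    # vehicle travel reads low on the accelerometer, walking high: the
    # movement boost is wildly variable, a poor proxy for travel time
    move_boost = np.where(moving, rng.uniform(0.1, 1.2, n_slots), 0.0)
    base_mag = np.where(awake, 1.2 * day_mult, 0.3) + move_boost
    mag = np.maximum(0.05, damp_accel * (base_mag + rng.normal(0, 0.15, n_slots)))
    vec = rng.normal(size=(n_slots, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    t_acc = slot_local - tz + rng.integers(60, 120, n_slots)
    accel = pd.DataFrame(
        {
            "participant_id": pid,
            "t": t_acc,
            "x": mag * vec[:, 0],
            "y": mag * vec[:, 1],
            "z": mag * vec[:, 2],
        }
    )

    # --- communication -------------------------------------------------------
    comm_mult = np.repeat(rng.lognormal(0, 0.4, n_days), _SLOTS_PER_DAY)
    rate = np.where(awake, np.where(second >= 17 * HOUR_S, 1.4, 1.0), 0.15)
    lam = damp_comm * comm_mult * rate * (_SLOT_S / 3600)
    counts = rng.poisson(lam)
    slots = np.repeat(np.arange(n_slots), counts)
    n_ev = len(slots)
    kinds = rng.choice(["call_in", "call_out", "sms"], size=n_ev, p=[0.35, 0.35, 0.30])
    dur = np.where(
        kinds == "sms", 0.0, np.round(rng.lognormal(4.3, 0.8, n_ev), 1)
    )
    contacts = rng.choice(20, size=n_ev, p=_norm(1.0 / np.arange(1, 21)))
    comm = pd.DataFrame(
        {
            "participant_id": pid,
            "t": slot_local[slots] - tz + rng.integers(0, _SLOT_S, n_ev),
            "kind": kinds,
            "duration": dur,
            "contact_id": [f"{pid}_c{c:02d}" for c in contacts],
        }
    )

    # --- device use ----------------------------------------------------------
    dev_mult = np.repeat(rng.lognormal(0, 0.4, n_days), _SLOTS_PER_DAY)
    sess_lam = dev_mult * np.where(awake, 2.2, 0.4) * (_SLOT_S / 3600)
    sess_counts = rng.poisson(sess_lam)
    s_slots = np.repeat(np.arange(n_slots), sess_counts)
    n_s = len(s_slots)
    s_start = slot_local[s_slots] - tz + rng.integers(0, _SLOT_S, n_s)
    s_dur = np.maximum(10, rng.lognormal(4.2, 0.9, n_s)).astype(int)
    dev_rows = [
        pd.DataFrame(
            {
                "participant_id": pid,
                "t": s_start,
                "kind": "screen_on",
                "app_id": None,
                "battery_pct": np.nan,
                "charging": None,
            }
        ),
        pd.DataFrame(
            {
                "participant_id": pid,
                "t": s_start + s_dur,
                "kind": "screen_off",
                "app_id": None,
                "battery_pct": np.nan,
                "charging": None,
            }
        ),
    ]
    app_counts = rng.poisson(1.2, n_s)
    a_sess = np.repeat(np.arange(n_s), app_counts)
    if len(a_sess):
        a_t = s_start[a_sess] + (rng.random(len(a_sess)) * s_dur[a_sess]).astype(int)
        dev_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "t": a_t,
                    "kind": "app_foreground",
                    "app_id": [f"app{a:02d}" for a in rng.integers(0, 15, len(a_sess))],
                    "battery_pct": np.nan,
                    "charging": None,
                }
            )
        )
    # battery: opportunistic charging — overnight only on ~70% of nights,
    # plus random daytime top-ups, with day-varying drain; the resulting
    # percentage trace is a poor clock
    per_day = DAY_S // cfg.battery_period_s
    n_bat = n_days * per_day
    t_bat = day0_local + np.arange(n_bat) * cfg.battery_period_s
    charging = np.zeros(n_bat, dtype=bool)
    for d in range(n_days):
        base = d * per_day
        if rng.random() < 0.7:  # overnight charge
            cs = rng.uniform(0, 2.5) * HOUR_S
            cl = rng.uniform(4, 6.5) * HOUR_S
            lo = base + int(cs // cfg.battery_period_s)
            hi = base + min(per_day, int((cs + cl) // cfg.battery_period_s) + 1)
            charging[lo:hi] = True
        for _ in range(int(rng.integers(0, 3))):  # daytime top-ups
            cs = rng.uniform(8, 22) * HOUR_S
            cl = rng.uniform(0.5, 1.5) * HOUR_S
            lo = base + int(cs // cfg.battery_period_s)
            hi = base + min(per_day, int((cs + cl) // cfg.battery_period_s) + 1)
            charging[lo:hi] = True
    drain = np.repeat(rng.uniform(2.0, 6.0, n_days), per_day)  # %/h
    rate_up = 40.0  # %/h while charging
    step = cfg.battery_period_s / HOUR_S
    delta = np.where(charging, rate_up * step, -drain * step)
    pct = np.empty(n_bat)
    level = rng.uniform(40, 100)
    for i in range(n_bat):  # battery level integrates; cheap at 48/day
        level = min(100.0, max(10.0, level + delta[i]))
        pct[i] = level
    pct = np.clip(pct + rng.normal(0, 2.0, n_bat), 0, 100)
    full = charging & (pct >= 97)
    pct[full] = 100.0
    dev_rows.append(
        pd.DataFrame(
            {
                "participant_id": pid,
                "t": t_bat - tz,
                "kind": "battery",
                "app_id": None,
                "battery_pct": np.round(pct, 1),
                "charging": charging,
            }
        )
    )
    device = pd.concat(dev_rows, ignore_index=True)

    # --- wifi ----------------------------------------------------------------
    w_step = cfg.wifi_period_s // _SLOT_S
    w_slots = np.arange(0, n_slots, w_step)
    w_anchor = sched[w_slots]
    w_kind = anchors["kind"].to_numpy()[w_anchor]
    w_mean = np.array([_WIFI_MEAN[k] for k in w_kind])
    w_mean[moving[w_slots]] = 8.0
    n_hot = np.minimum(rng.poisson(w_mean), _POOL)
    ids = [
        ";".join(f"{pid}_a{a}_h{j:02d}" for j in range(n)) if n else ""
        for a, n in zip(w_anchor, n_hot)
    ]
    wifi = pd.DataFrame(
        {
            "participant_id": pid,
            "t": slot_local[w_slots] - tz + rng.integers(0, 60, len(w_slots)),
            "n_unique_hotspots": n_hot,
            "hotspot_ids": ids,
        }
    )
    return gps, accel, comm, device, wifi, anchors


def inject_missingness(
    streams: SensorStreams, cfg: CohortConfig, rng: np.random.Generator
) -> tuple[SensorStreams, pd.DataFrame]:
    """Remove spans of records per the configured gap model.

    Returns the thinned streams and a log of removed spans (participant,
    stream, start, length).  A zero-rate config returns the input unchanged.
    """
    miss = cfg.missingness
    gaps = []
    pids = streams.participants["participant_id"].to_numpy()
    tz = cfg.tz_offset_s
    day0 = STUDY_DAY0 * DAY_S

    for pid in pids:
        for d in range(cfg.n_days):
            lo_l = day0 + d * DAY_S
            if rng.random() < miss["gps_day_off_p"]:
                gaps.append((pid, "gps", lo_l, DAY_S))
            if rng.random() < miss["blackout_day_p"]:
                length = rng.uniform(*miss["blackout_hours"]) * HOUR_S
                start = lo_l + rng.uniform(0, DAY_S - length)
                for s in ("gps", "accel", "comm", "device", "wifi"):
                    gaps.append((pid, s, start, length))
            for s in ("gps", "accel", "comm", "device", "wifi"):
                for _ in range(rng.poisson(miss["short_gaps_per_day"])):
                    length = rng.uniform(*miss["short_gap_minutes"]) * 60
                    start = lo_l + rng.uniform(0, DAY_S - length)
                    gaps.append((pid, s, start, length))

    gap_df = pd.DataFrame(gaps, columns=["participant_id", "stream", "start_local_s", "length_s"])
    if gap_df.empty:
        return streams, gap_df

    out = {}
    for name in ("gps", "accel", "comm", "device", "wifi"):
        df = streams.stream(name)
        if not len(df):
            out[name] = df
            continue
        keep = np.ones(len(df), dtype=bool)
        sub = gap_df[gap_df["stream"] == name]
        t_local = df["t"].to_numpy(dtype=float) + tz
        pid_col = df["participant_id"].to_numpy()
        for pid, g in sub.groupby("participant_id"):
            m = pid_col == pid
            tl = t_local[m]
            drop = np.zeros(len(tl), dtype=bool)
            for s, L in zip(g["start_local_s"].to_numpy(), g["length_s"].to_numpy()):
                lo, hi = np.searchsorted(tl, [s, s + L])
                drop[lo:hi] = True
            idx = np.flatnonzero(m)
            keep[idx[drop]] = False
        out[name] = df.loc[keep].reset_index(drop=True)
    streams2 = SensorStreams(
        ema=streams.ema, participants=streams.participants, **out
    )
    return streams2, gap_df


def simulate_cohort(
    cfg: Optional[CohortConfig] = None,
) -> tuple[SensorStreams, GroundTruth]:
    """Generate a full synthetic cohort: sensor streams (with missingness),
    self-reports, and the ground truth behind them.  Deterministic in
    ``cfg.seed``."""
    cfg = cfg or CohortConfig()
    root = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(4 + cfg.n_participants)]
    r_part, r_events, r_miss = rngs[0], rngs[1], rngs[2]

    participants = make_participants(cfg, r_part)
    events = sample_events(cfg, r_events, participants)

    anchor_frames, g, a, c, d, w = [], [], [], [], [], []
    for i, pid in enumerate(participants["participant_id"]):
        rng_i = rngs[4 + i]
        anchors = _make_anchors(cfg, rng_i, pid)
        ev_i = events[events["participant_id"] == pid]
        gps, accel, comm, device, wifi, anchors = _synth_participant(
            cfg, rng_i, pid, anchors, ev_i
        )
        anchor_frames.append(anchors)
        g.append(gps), a.append(accel), c.append(comm), d.append(device), w.append(wifi)

    def cat(frames):
        if not frames:
            return pd.DataFrame()
        df = pd.concat(frames, ignore_index=True)
        return df.sort_values(["participant_id", "t"], kind="mergesort").reset_index(drop=True)

    streams = SensorStreams(
        gps=cat(g),
        accel=cat(a),
        comm=cat(c),
        device=cat(d),
        wifi=cat(w),
        ema=events_to_ema(events),
        participants=participants,
    )
    streams, gap_df = inject_missingness(streams, cfg, r_miss)
    truth = GroundTruth(
        events=events,
        anchors=pd.concat(anchor_frames, ignore_index=True),
        gaps=gap_df,
        config=cfg,
    )
    return streams, truth
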