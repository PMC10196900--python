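"""From raw streams and self-reports to labeled, windowed events.

A reported day becomes one *event*: non-drinking (N), low-risk drinking (D)
or binge (BDE; >=4 drinks for women, >=5 for men per occasion).  Each event
anchors a 24-hour lookback of 15-minute epochs ending at the (snapped)
drinking onset; an analysis window of ``w`` hours ending ``d`` hours before
onset is cut from that grid, so no feature can see data from the ``d``-hour
separation period.  Non-drinking days get a pseudo-onset drawn uniformly
from the 18:00-24:00 evening grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SensorStreams
from .timeutil import DAY_S, EPOCH_S, HOUR_S, day_of_week, snap_to_epoch

__all__ = [
    "CLASSES",
    "LabelingRules",
    "WindowConfig",
    "EpochSlice",
    "label_event",
    "pseudo_onset",
    "build_events",
    "classify_day",
    "epochize",
    "extract_window",
    "interpolate_gaps",
    "apply_inclusion_exclusion",
]

CLASSES = ("N", "D", "BDE")
LABEL_CODE = {c: i for i, c in enumerate(CLASSES)}

#: default weekend partition; the observed binge mass concentrates Fri-Sun
WEEKEND_DAYS = frozenset({4, 5, 6})


@dataclass(frozen=True)
class LabelingRules:
    female_bde_threshold: int = 4
    male_bde_threshold: int = 5

    def __post_init__(self):
        if self.female_bde_threshold < 1 or self.male_bde_threshold < 1:
            raise ValueError("binge thresholds must be >= 1")

    def threshold(self, sex: str) -> int:
        if sex == "female":
            return self.female_bde_threshold
        if sex == "male":
            return self.male_bde_threshold
        raise ValueError(f"unknown sex: {sex!r}")


def label_event(n_drinks: int, sex: str, rules: LabelingRules = LabelingRules()) -> str:
    """0 drinks -> N, 1..threshold-1 -> D, >= threshold -> BDE."""
    if n_drinks < 0:
        raise ValueError("n_drinks must be non-negative")
    thr = rules.threshold(sex)
    if n_drinks == 0:
        return "N"
    return "BDE" if n_drinks >= thr else "D"


def pseudo_onset(day_local_s: int, rng: np.random.Generator) -> int:
    """A 'start of the non-drinking event': uniform over the 15-minute grid
    in [18:00, 24:00) of the given local day."""
    slot = int(rng.integers(0, 24))  # 24 quarter-hours in 6 evening hours
    return int(day_local_s - day_local_s % DAY_S + 18 * HOUR_S + slot * EPOCH_S)


@dataclass(frozen=True)
class WindowConfig:
    """Analysis window length ``w`` and prediction distance ``d`` (hours).

    All data are drawn from the 24 h before onset, hence ``w + d <= 24``.
    """

    w_hours: int
    d_hours: int

    def __post_init__(self):
        if self.w_hours <= 0 or self.d_hours <= 0:
            raise ValueError("w_hours and d_hours must be positive")
        if self.w_hours + self.d_hours > 24:
            raise ValueError("w + d must not exceed 24 hours")

    @property
    def tag(self) -> str:
        return f"W{self.w_hours}D{self.d_hours}"


def classify_day(day_of_week_idx, weekend_days=WEEKEND_DAYS):
    """Map Monday=0..Sunday=6 to 'weekday'/'weekend' (partition configurable)."""
    arr = np.asarray(day_of_week_idx)
    out = np.where(np.isin(arr, list(weekend_days)), "weekend", "weekday")
    return out.item() if np.isscalar(day_of_week_idx) else out


def build_events(
    streams: SensorStreams,
    rules: LabelingRules = LabelingRules(),
    seed: int = 0,
    weekend_days=WEEKEND_DAYS,
) -> pd.DataFrame:
    """Label every self-report and anchor it with a (pseudo-)onset.

    Returns one row per event: participant, date, local onset (raw and
    snapped to the 15-minute grid), drink count, class label, weekday /
    weekend, and whether the onset is a sampled pseudo-onset.
    """
    rng = np.random.default_rng(seed)
    ema = streams.ema
    parts = streams.participants.set_index("participant_id")
    rows = []
    for r in ema.itertuples():
        sex = parts.loc[r.participant_id, "sex"]
        tz = int(parts.loc[r.participant_id, "tz_offset_s"])
        n_drinks = int(r.n_drinks) if bool(r.drank) else 0
        label = label_event(n_drinks, sex, rules)
        day_local = (
            pd.Timestamp(r.report_date) - pd.Timestamp("1970-01-01")
        ).days * DAY_S
        if bool(r.drank):
            hh, mm = str(r.start_time).split(":")
            onset = day_local + int(hh) * HOUR_S + int(mm) * 60
            pseudo = False
        else:
            onset = pseudo_onset(day_local, rng)
            pseudo = True
        rows.append(
            (
                r.participant_id,
                str(r.report_date),
                tz,
                onset,
                int(snap_to_epoch(onset)),
                n_drinks,
                label,
                pseudo,
            )
        )
    ev = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "date",
            "tz_offset_s",
            "onset_local_s",
            "onset_snap_s",
            "n_drinks",
            "label",
            "pseudo",
        ],
    )
    ev["day_of_week"] = day_of_week(ev["onset_local_s"].to_numpy())
    ev["day_class"] = classify_day(ev["day_of_week"].to_numpy(), weekend_days)
    ev["exclusion_reason"] = ""
    return ev


@dataclass
class EpochSlice:
    """An ordered run of 15-minute epoch slots for one event."""

    participant_id: str
    starts_local_s: np.ndarray  # epoch start times, local seconds
    missing: np.ndarray  # True where no sensor stream has any record
    onset_snap_s: int
    tz_offset_s: int

    def __len__(self):
        return len(self.starts_local_s)

    @property
    def span(self) -> tuple[int, int]:
        """(start, end) of the covered interval in local seconds."""
        return int(self.starts_local_s[0]), int(self.starts_local_s[-1]) + EPOCH_S


def _participant_times(streams: SensorStreams, pid: str, tz: int) -> np.ndarray:
    """Sorted local timestamps of *all* sensor records for one participant."""
    ts = []
    for name in ("gps", "accel", "comm", "device", "wifi"):
        df = streams.stream(name)
        if len(df):
            ts.append(df.loc[df["participant_id"] == pid, "t"].to_numpy(dtype=float) + tz)
    if not ts:
        return np.empty(0)
    return np.sort(np.concatenate(ts))


def epochize(event, streams: SensorStreams = None, times: np.ndarray = None) -> EpochSlice:
    """The 96 15-minute epochs covering the 24 h before the event onset.

    The onset snaps down to its containing epoch boundary; epochs with no
    sensor records at all are flagged missing rather than fabricated.
    ``event`` is a row (namedtuple/Series) from :func:`build_events`;
    ``times`` may supply the participant's pre-sorted local record
    timestamps in place of ``streams``.
    """
    onset = int(event.onset_snap_s)
    tz = int(event.tz_offset_s)
    starts = np.arange(onset - DAY_S, onset, EPOCH_S, dtype=np.int64)
    if times is not None:
        t_all = times
    elif streams is not None:
        t_all = _participant_times(streams, event.participant_id, tz)
    else:
        raise ValueError("either streams or times must be provided")
    counts = np.diff(np.searchsorted(t_all, np.append(starts, onset)))
    return EpochSlice(
        participant_id=event.participant_id,
        starts_local_s=starts,
        missing=counts == 0,
        onset_snap_s=onset,
        tz_offset_s=tz,
    )


def extract_window(epochs: EpochSlice, cfg: WindowConfig) -> EpochSlice:
    """The analysis slice [onset - (w+d), onset - d): exactly ``4 w`` epochs,
    all strictly before the prediction time ``onset - d``."""
    onset = epochs.onset_snap_s
    lo = onset - (cfg.w_hours + cfg.d_hours) * HOUR_S
    hi = onset - cfg.d_hours * HOUR_S
    m = (epochs.starts_local_s >= lo) & (epochs.starts_local_s < hi)
    return EpochSlice(
        participant_id=epochs.participant_id,
        starts_local_s=epochs.starts_local_s[m],
        missing=epochs.missing[m],
        onset_snap_s=onset,
        tz_offset_s=epochs.tz_offset_s,
    )


def interpolate_gaps(
    df: pd.DataFrame,
    value_cols,
    cadence_s: float,
    max_gap_s: float = 15 * 60,
) -> pd.DataFrame:
    """Fill short silences in a numeric stream.

    A gap longer than the nominal cadence but at most ``max_gap_s`` is
    filled at the cadence with the mean of the two flanking records; longer
    gaps are left untouched.  The input must be sorted by
    ``(participant_id, t)``; non-value columns of inserted rows are copied
    from the left flank.
    """
    if not len(df):
        return df
    pieces = [df]
    for pid, g in df.groupby("participant_id", sort=False):
        t = g["t"].to_numpy(dtype=float)
        dt = np.diff(t)
        gap_idx = np.flatnonzero((dt > 1.5 * cadence_s) & (dt <= max_gap_s))
        for i in gap_idx:
            new_t = np.arange(t[i] + cadence_s, t[i + 1] - 1e-9, cadence_s)
            if not len(new_t):
                continue
            left = g.iloc[i]
            right = g.iloc[i + 1]
            block = pd.DataFrame([left] * len(new_t))
            block["t"] = new_t
            for c in value_cols:
                block[c] = 0.5 * (left[c] + right[c])
            pieces.append(block)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["participant_id", "t"], kind="mergesort").reset_index(drop=True)


DEFAULT_KEY_STREAMS = ("gps", "accel")


def apply_inclusion_exclusion(
    events: pd.DataFrame,
    streams: SensorStreams,
    key_streams=DEFAULT_KEY_STREAMS,
    min_days: int = 3,
    max_key_missing_frac: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop events with no GPS in their 24-h lookback, events whose key
    feature sources are missing in more than half of their epochs, and
    participants left with fewer than ``min_days`` qualifying days.

    Returns ``(events with exclusion_reason filled, exclusion log)``; kept
    rows have an empty reason.
    """
    ev = events.copy()
    reasons = np.array([""] * len(ev), dtype=object)

    # per-participant sorted local times for the key streams
    cache: dict[tuple[str, str], np.ndarray] = {}

    def times(pid, name, tz):
        key = (pid, name)
        if key not in cache:
            df = streams.stream(name)
            sel = df.loc[df["participant_id"] == pid, "t"].to_numpy(dtype=float) + tz
            cache[key] = np.sort(sel)
        return cache[key]

    for i, event in enumerate(ev.itertuples()):
        onset = int(event.onset_snap_s)
        tz = int(event.tz_offset_s)
        gps_t = times(event.participant_id, "gps", tz)
        lo, hi = np.searchsorted(gps_t, [onset - DAY_S, onset])
        if hi - lo == 0:
            reasons[i] = "no_gps"
            continue
        edges = np.arange(onset - DAY_S, onset + 1, EPOCH_S)
        missing_any = np.zeros(96, dtype=bool)
        for name in key_streams:
            t_s = times(event.participant_id, name, tz)
            counts = np.diff(np.searchsorted(t_s, edges))
            missing_any |= counts == 0
        if missing_any.mean() > max_key_missing_frac:
            reasons[i] = "key_features_missing"

    ev["exclusion_reason"] = reasons
    kept = ev[ev["exclusion_reason"] == ""]
    qualifying = kept.groupby("participant_id")["date"].nunique()
    bad = set(qualifying[qualifying < min_days].index) | (
        set(ev["participant_id"]) - set(qualifying.index)
    )
    m = ev["participant_id"].isin(bad) & (ev["exclusion_reason"] == "")
    ev.loc[m, "exclusion_reason"] = "participant_few_days"

    log = ev.loc[ev["exclusion_reason"] != "", ["participant_id", "date", "label", "exclusion_reason"]]
    return ev, log.reset_index(drop=True)
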