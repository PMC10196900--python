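"""Stream schemas and tabular I/O.

Raw sensor data live in one long-format CSV per stream type
(``gps.csv``, ``accel.csv``, ``comm.csv``, ``device.csv``, ``wifi.csv``)
plus the self-report table ``ema.csv`` and the roster ``participants.csv``.
Timestamps are UTC epoch seconds; ``participants.csv`` carries the fixed
``tz_offset_s`` used for all local-clock logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensorStreams",
    "ValidationReport",
    "SchemaError",
    "STREAM_FILES",
    "read_streams",
    "validate_streams",
    "write_fixture",
]

COMM_KINDS = {"call_in", "call_out", "sms"}
DEVICE_KINDS = {"screen_on", "screen_off", "app_foreground", "battery"}
SEXES = {"female", "male"}

#: file name -> ordered column list (the on-disk schema contract)
STREAM_FILES = {
    "gps": ["participant_id", "t", "lat", "lon", "accuracy"],
    "accel": ["participant_id", "t", "x", "y", "z"],
    "comm": ["participant_id", "t", "kind", "duration", "contact_id"],
    "device": ["participant_id", "t", "kind", "app_id", "battery_pct", "charging"],
    "wifi": ["participant_id", "t", "n_unique_hotspots", "hotspot_ids"],
    "ema": [
        "participant_id",
        "report_date",
        "drank",
        "n_drinks",
        "start_time",
        "end_time",
        "end_next_day",
    ],
    "participants": ["participant_id", "sex", "enrolled_days", "tz_offset_s"],
}

SENSOR_STREAMS = ("gps", "accel", "comm", "device", "wifi")


class SchemaError(ValueError):
    """A row or file violates the documented stream schema."""


@dataclass
class SensorStreams:
    """All tabular inputs for a cohort, keyed by stream type.

    Each sensor frame is sorted by ``(participant_id, t)``; ``ema`` and
    ``participants`` are plain tables.
    """

    gps: pd.DataFrame = field(default_factory=lambda: _empty("gps"))
    accel: pd.DataFrame = field(default_factory=lambda: _empty("accel"))
    comm: pd.DataFrame = field(default_factory=lambda: _empty("comm"))
    device: pd.DataFrame = field(default_factory=lambda: _empty("device"))
    wifi: pd.DataFrame = field(default_factory=lambda: _empty("wifi"))
    ema: pd.DataFrame = field(default_factory=lambda: _empty("ema"))
    participants: pd.DataFrame = field(default_factory=lambda: _empty("participants"))

    def stream(self, name: str) -> pd.DataFrame:
        if name not in STREAM_FILES:
            raise KeyError(f"unknown stream type: {name!r}")
        return getattr(self, name)

    def tz_offset(self, participant_id: str) -> int:
        row = self.participants.loc[
            self.participants["participant_id"] == participant_id
        ]
        if row.empty:
            raise KeyError(f"unknown participant: {participant_id!r}")
        return int(row["tz_offset_s"].iloc[0])

    def n_records(self) -> dict:
        return {name: len(self.stream(name)) for name in SENSOR_STREAMS}


def _empty(name: str) -> pd.DataFrame:
    return pd.DataFrame(columns=STREAM_FILES[name])


def _sort_stream(df: pd.DataFrame) -> pd.DataFrame:
    if "t" in df.columns and len(df):
        df = df.sort_values(["participant_id", "t"], kind="mergesort")
    return df.reset_index(drop=True)


def _check_rows(name: str, df: pd.DataFrame, path) -> None:
    """Raise SchemaError naming the first offending data line (1-based,
    excluding the header)."""

    def offend(mask, msg):
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 2  # +header +1-based
            raise SchemaError(f"{path}: line {line}: {msg}")

    if name == "gps":
        offend(~df["lat"].between(-90, 90), "lat outside [-90, 90]")
        offend(~df["lon"].between(-180, 180), "lon outside [-180, 180]")
    elif name == "accel":
        offend(
            ~np.isfinite(df[["x", "y", "z"]]).all(axis=1),
            "non-finite acceleration component",
        )
    elif name == "comm":
        offend(~df["kind"].isin(COMM_KINDS), "unknown comm kind")
        offend(df["duration"] < 0, "negative call duration")
    elif name == "device":
        offend(~df["kind"].isin(DEVICE_KINDS), "unknown device kind")
        is_batt = df["kind"] == "battery"
        offend(is_batt & df["battery_pct"].isna(), "battery event without battery_pct")
        offend(
            (df["kind"] == "app_foreground") & df["app_id"].isna(),
            "app event without app_id",
        )
    elif name == "wifi":
        offend(df["n_unique_hotspots"] < 0, "negative hotspot count")
    elif name == "ema":
        offend(
            (~df["drank"].astype(bool)) & (df["n_drinks"] != 0),
            "n_drinks must be 0 when drank is false",
        )
        offend(df["n_drinks"] < 0, "negative n_drinks")
    elif name == "participants":
        offend(~df["sex"].isin(SEXES), "sex must be female or male")


def read_streams(path) -> SensorStreams:
    """Read a fixture directory of per-type CSV files.

    Missing files yield empty streams; an empty directory yields an empty
    container with a warning.  Rows are sorted ascending by timestamp within
    each participant regardless of on-disk order.
    """
    path = Path(path)
    found = {}
    for name, cols in STREAM_FILES.items():
        f = path / f"{name}.csv"
        if not f.exists():
            continue
        try:
            df = pd.read_csv(f)
        except Exception as exc:  # malformed CSV
            raise SchemaError(f"{f}: cannot parse: {exc}") from exc
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{f}: missing columns {missing}")
        df = df[cols]
        _check_rows(name, df, f)
        found[name] = _sort_stream(df)
    if not found:
        warnings.warn(f"no stream files found under {path}", stacklevel=2)
    unknown = {
        f.stem for f in path.glob("*.csv") if f.stem not in STREAM_FILES
    }
    if unknown:
        raise SchemaError(f"unknown stream type file(s): {sorted(unknown)}")
    return SensorStreams(**found)


@dataclass
class ValidationReport:
    counts: pd.DataFrame  # participant_id x stream -> n records
    gaps: pd.DataFrame  # participant_id, stream, gap_start, gap_s
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_streams(streams: SensorStreams, gap_threshold_s: int = 1800) -> ValidationReport:
    """Report per-participant record counts, silences longer than
    ``gap_threshold_s`` (default 30 min, the app's sync interval), and
    invariant violations.  Report-only: never raises."""
    counts = {}
    gaps = []
    violations = []
    for name in SENSOR_STREAMS:
        df = streams.stream(name)
        counts[name] = df.groupby("participant_id", sort=True).size() if len(df) else pd.Series(dtype=int)
        for pid, g in df.groupby("participant_id", sort=True):
            t = g["t"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                violations.append((pid, name, "timestamps not sorted"))
            dup = np.diff(t) == 0
            if name in ("gps", "accel", "wifi") and dup.any():
                violations.append((pid, name, "duplicate timestamps"))
            dt = np.diff(t)
            for i in np.flatnonzero(dt > gap_threshold_s):
                gaps.append((pid, name, float(t[i]), float(dt[i])))
    count_df = pd.DataFrame(counts).fillna(0).astype(int)
    gap_df = pd.DataFrame(gaps, columns=["participant_id", "stream", "gap_start", "gap_s"])
    return ValidationReport(count_df, gap_df, violations)


def write_fixture(streams: SensorStreams, path) -> None:
    """Serialize a cohort so that ``read_streams`` round-trips it exactly.

    Participants absent from a stream simply do not appear in that file; an
    empty cohort still writes valid headed files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, cols in STREAM_FILES.items():
        df = streams.stream(name)
        df.to_csv(path / f"{name}.csv", index=False, columns=cols, float_format="%.10g")
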