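"""Clock arithmetic on epoch-second timestamps.

All raw records carry UTC epoch seconds; each participant has a fixed UTC
offset that converts to local clock time.  Every time-of-day rule in the
pipeline (onset hours, the 15-minute epoch grid, day-of-week encoding)
operates on local seconds, which sidesteps datetime/DST machinery while
keeping the semantics of "5 PM local".
"""

from __future__ import annotations

import numpy as np

EPOCH_S = 900  # one 15-minute epoch
HOUR_S = 3600
DAY_S = 86400
WEEK_S = 7 * DAY_S

# 1970-01-01 was a Thursday; with Monday=0 that is day-of-week 3.
_UNIX_EPOCH_DOW = 3


def to_local(t, tz_offset_s):
    """UTC epoch seconds -> local seconds (same scale, shifted)."""
    return np.asarray(t) + tz_offset_s


def to_utc(local_s, tz_offset_s):
    return np.asarray(local_s) - tz_offset_s


def day_index(local_s):
    """Whole local days since the UNIX epoch."""
    return np.floor_divide(np.asarray(local_s, dtype=np.int64), DAY_S)


def day_of_week(local_s):
    """Monday=0 .. Sunday=6."""
    return (day_index(local_s) + _UNIX_EPOCH_DOW) % 7


def second_of_day(local_s):
    return np.mod(np.asarray(local_s, dtype=np.int64), DAY_S)


def hour_of_day(local_s):
    return second_of_day(local_s) // HOUR_S


def snap_to_epoch(local_s):
    """Snap down to the containing 15-minute boundary."""
    return np.asarray(local_s, dtype=np.int64) - np.mod(
        np.asarray(local_s, dtype=np.int64), EPOCH_S
    )


def iso_date(local_s) -> str:
    """Calendar date of a local timestamp (for reports and CSV keys)."""
    import datetime as _dt

    d = int(day_index(local_s))
    return (_dt.date(1970, 1, 1) + _dt.timedelta(days=d)).isoformat()
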