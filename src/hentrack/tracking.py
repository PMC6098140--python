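"""Tracker-log parsing, cleaning, transition extraction and daily windowing.

Turns raw 1 Hz zone registrations into the two derived products every
analysis consumes: per-zone transition records (entry time + completed
dwell) and fixed-window daily occupancy series (hen-days).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_WINDOW,
    N_ZONES,
    SECONDS_PER_DAY,
    AnalysisWindow,
    HenDay,
    RegistrationLog,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionRecord",
    "parse_log",
    "clean_log",
    "to_transitions",
    "build_hen_days",
    "transitions_frame",
    "write_henday_rle",
    "read_henday_rle",
]


@dataclass(frozen=True)
class TransitionRecord:
    """Entry into ``to_zone``; ``from_zone`` None at the covered span's start.

    ``dwell_s`` is the completed stay in ``from_zone`` (0 for the opening
    record, which is an occupancy, not a visit).
    """

    hen_id: str
    day_index: int
    second_of_day: int
    from_zone: int | None
    to_zone: int
    dwell_s: int


# --------------------------------------------------------------------------
# parsing


def parse_log(path, hen_id: str | None = None) -> RegistrationLog:
    """Parse a receiver CSV (columns date, time, zone) into a RegistrationLog.

    Day indices are 1-based from the earliest date present.  Duplicate
    seconds collapse to the last row; rows are re-ordered by timestamp.
    Malformed rows and zone codes outside 1-5 raise with the offending
    line number (header = line 1).
    """
    df = pd.read_csv(path, dtype=str)
    required = {"date", "time", "zone"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")

    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    parts = df["time"].str.extract(
        r"^(?P<h>[01]\d|2[0-3]):(?P<m>[0-5]\d):(?P<s>[0-5]\d)$"
    )
    times = (
        pd.to_numeric(parts["h"]) * 3600
        + pd.to_numeric(parts["m"]) * 60
        + pd.to_numeric(parts["s"])
    )
    zones = pd.to_numeric(df["zone"], errors="coerce")
    for name, col in (("date", dates), ("time", times), ("zone", zones)):
        bad = col.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path}: malformed {name} at line {line}")
    out_of_range = (zones < 1) | (zones > N_ZONES) | (zones != zones.astype(int))
    if out_of_range.any():
        line = int(np.flatnonzero(out_of_range.to_numpy())[0]) + 2
        raise ValueError(
            f"{path}: zone outside 1..{N_ZONES} at line {line}"
        )

    day_index = (dates - dates.min()).dt.days.to_numpy() + 1
    second = times.astype(np.int64).to_numpy()

    if hen_id is None:
        name = getattr(path, "stem", None) or str(path).rsplit("/", 1)[-1]
        name = str(name)
        if name.endswith(".csv"):
            name = name[:-4]
        hen_id = name.removeprefix("hen_")

    log = RegistrationLog(hen_id=str(hen_id))
    frame = pd.DataFrame(
        {"day": day_index, "sec": second, "zone": zones.astype(np.int8)}
    )
    # stable sort + keep last: duplicate seconds collapse to the last row
    frame = frame.sort_values(["day", "sec"], kind="stable")
    frame = frame.drop_duplicates(["day", "sec"], keep="last")
    for day, grp in frame.groupby("day", sort=True):
        log.add_day(int(day), grp["sec"].to_numpy(np.int32), grp["zone"].to_numpy(np.int8))
    return log


# --------------------------------------------------------------------------
# cleaning


def _runs(zones: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode: (start indices, run values); lengths from diffs."""
    change = np.flatnonzero(np.diff(zones) != 0) + 1
    starts = np.concatenate(([0], change))
    return starts, zones[starts]


def _debounce(zones: np.ndarray, min_dwell_s: int) -> np.ndarray:
    """Reassign runs shorter than min_dwell_s to the preceding zone
    (the following zone for a short run at the start); repeat to fixpoint."""
    z = zones.copy()
    while True:
        starts, vals = _runs(z)
        lengths = np.diff(np.concatenate((starts, [z.size])))
        short = np.flatnonzero(lengths < min_dwell_s)
        if short.size == 0 or vals.size == 1:
            return z
        i = int(short[0])
        lo = starts[i]
        hi = lo + lengths[i]
        z[lo:hi] = vals[i - 1] if i > 0 else vals[i + 1]


def clean_log(
    log: RegistrationLog, max_gap_s: int = 60, min_dwell_s: int = 0
) -> RegistrationLog:
    """Fill short sensor dropouts and debounce sub-threshold blips.

    Gaps of at most ``max_gap_s`` missing seconds are forward-filled with
    the last registered zone; longer gaps stay missing.  Runs shorter than
    ``min_dwell_s`` are absorbed into the surrounding zone.  Idempotent.
    """
    out = RegistrationLog(hen_id=log.hen_id)
    for day in log.day_indices:
        sec, zon = log.days[day]
        if sec.size == 0:
            out.add_day(day, sec, zon)
            continue
        gaps = np.diff(sec) - 1
        fill = (gaps > 0) & (gaps <= max_gap_s)
        segments_s = [sec]
        segments_z = [zon]
        for i in np.flatnonzero(fill):
            filled = np.arange(sec[i] + 1, sec[i + 1], dtype=np.int32)
            segments_s.append(filled)
            segments_z.append(np.full(filled.size, zon[i], dtype=np.int8))
        all_s = np.concatenate(segments_s)
        order = np.argsort(all_s, kind="stable")
        all_s = all_s[order]
        all_z = np.concatenate(segments_z)[order]

        if min_dwell_s > 1:
            # debounce per contiguous stretch so gaps stay untouched
            breaks = np.flatnonzero(np.diff(all_s) > 1) + 1
            bounds = np.concatenate(([0], breaks, [all_s.size]))
            pieces = []
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                pieces.append(_debounce(all_z[lo:hi], min_dwell_s))
            all_z = np.concatenate(pieces)
        out.add_day(day, all_s, all_z)
    return out


# --------------------------------------------------------------------------
# transitions


def to_transitions(log: RegistrationLog) -> list[TransitionRecord]:
    """One record per zone change; dwell times partition the covered span.

    Each day opens with a ``from_zone=None`` record for the zone occupied
    at the first covered second (an occupancy, not a visit).  The final,
    still-open bout produces no record; its length is the remainder of the
    covered span.
    """
    records: list[TransitionRecord] = []
    for day in log.day_indices:
        sec, zon = log.days[day]
        if sec.size == 0:
            continue
        if np.any(np.diff(sec) != 1):
            raise ValueError(
                f"hen {log.hen_id} day {day}: covered span has internal gaps; "
                "clean_log first"
            )
        records.append(
            TransitionRecord(log.hen_id, day, int(sec[0]), None, int(zon[0]), 0)
        )
        change = np.flatnonzero(np.diff(zon) != 0) + 1
        prev = 0
        for idx in change:
            records.append(
                TransitionRecord(
                    hen_id=log.hen_id,
                    day_index=day,
                    second_of_day=int(sec[idx]),
                    from_zone=int(zon[prev]),
                    to_zone=int(zon[idx]),
                    dwell_s=int(idx - prev),
                )
            )
            prev = int(idx)
    return records


def transitions_frame(records: list[TransitionRecord]) -> pd.DataFrame:
    """Transition records as a tidy frame (delimited-text friendly)."""
    return pd.DataFrame(
        {
            "hen_id": [r.hen_id for r in records],
            "day": [r.day_index for r in records],
            "second_of_day": [r.second_of_day for r in records],
            "from_zone": [r.from_zone if r.from_zone is not None else "" for r in records],
            "to_zone": [r.to_zone for r in records],
            "dwell_s": [r.dwell_s for r in records],
        }
    )


# --------------------------------------------------------------------------
# daily windowing


def build_hen_days(
    logs: list[RegistrationLog],
    window: AnalysisWindow = DEFAULT_WINDOW,
    days: list[int] | None = None,
) -> list[HenDay]:
    """Fixed-window daily datasets, one per hen per selected day.

    ``days=None`` selects every day present in a log.  A hen-day whose
    window is not fully covered is excluded with a logged warning.
    """
    hendays: list[HenDay] = []
    for log in logs:
        selected = days if days is not None else log.day_indices
        for day in selected:
            if day not in log.days:
                logger.warning("hen %s day %s: absent from log; skipped", log.hen_id, day)
                continue
            sec, zon = log.days[day]
            lo = np.searchsorted(sec, window.start_s)
            hi = np.searchsorted(sec, window.end_s)
            wsec = sec[lo:hi]
            if wsec.size != window.length:
                logger.warning(
                    "hen %s day %s: window covered for %d of %d s; excluded",
                    log.hen_id,
                    day,
                    wsec.size,
                    window.length,
                )
                continue
            hendays.append(
                HenDay(
                    hen_id=log.hen_id,
                    day_index=day,
                    series=zon[lo:hi],
                    window=window,
                )
            )
    return hendays


# --------------------------------------------------------------------------
# compact fixture format


def write_henday_rle(henday: HenDay, path) -> None:
    """Run-length encoded hen-day: header line, then ``zone,length`` rows."""
    starts = np.concatenate(
        ([0], np.flatnonzero(np.diff(henday.series) != 0) + 1)
    )
    lengths = np.diff(np.concatenate((starts, [henday.series.size])))
    with open(path, "w") as fh:
        fh.write(
            f"#henday {henday.hen_id} {henday.day_index} "
            f"{henday.window.start_s} {henday.window.end_s}\n"
        )
        for s, n in zip(starts, lengths):
            fh.write(f"{int(henday.series[s])},{int(n)}\n")


def read_henday_rle(path) -> HenDay:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 5 or header[0] != "#henday":
            raise ValueError(f"{path}: not a run-length hen-day file")
        hen_id, day, start_s, end_s = header[1], int(header[2]), int(header[3]), int(header[4])
        chunks = []
        for line in fh:
            zone, length = line.strip().split(",")
            chunks.append(np.full(int(length), int(zone), dtype=np.int8))
    return HenDay(
        hen_id=hen_id,
        day_index=day,
        series=np.concatenate(chunks),
        window=AnalysisWindow(start_s, end_s),
    )
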