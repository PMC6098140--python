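"""Shared domain types for aviary zone-tracking analyses.

The housing system is divided into five functional zones; a legband
receiver registers the zone a hen occupies once per second.  Analyses run
on fixed daily windows of that 1 Hz occupancy series.

Zone codes (fixed, total mapping):

    1  wintergarden (roofed outdoor run, pophole-gated)
    2  litter area
    3  lower tier (feed, water)
    4  nestbox tier
    5  upper tier (feed, water, roosting)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

ZONES: tuple[int, ...] = (1, 2, 3, 4, 5)
N_ZONES: int = 5
ZONE_NAMES: dict[int, str] = {
    1: "Wintergarden",
    2: "Litter area",
    3: "Lower tier",
    4: "Nestbox tier",
    5: "Upper tier",
}

SECONDS_PER_DAY: int = 86400


def seconds_of_day(h: int, m: int = 0, s: int = 0) -> int:
    """Seconds since midnight for a clock time ``h:m:s``."""
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
        raise ValueError(f"invalid clock time {h:02d}:{m:02d}:{s:02d}")
    return h * 3600 + m * 60 + s


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open daily window ``[start_s, end_s)`` in seconds-of-day.

    The default covers the lit period 02:00:00-16:59:59 inclusive, i.e.
    [02:00:00, 17:00:00) = 54,000 one-second samples.
    """

    start_s: int = seconds_of_day(2)
    end_s: int = seconds_of_day(17)

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s <= SECONDS_PER_DAY):
            raise ValueError(
                f"invalid analysis window [{self.start_s}, {self.end_s})"
            )

    @property
    def length(self) -> int:
        return self.end_s - self.start_s


DEFAULT_WINDOW = AnalysisWindow()


@dataclass
class RegistrationLog:
    """Per-hen 1 Hz registrations, grouped by 1-based day index.

    ``days`` maps day_index -> (seconds, zones): parallel arrays of
    seconds-of-day (strictly increasing, at most one sample per second)
    and zone codes.  Seconds may be non-contiguous after sensor dropouts.
    """

    hen_id: str
    days: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_day(self, day_index: int, seconds: np.ndarray, zones: np.ndarray) -> None:
        seconds = np.asarray(seconds, dtype=np.int32)
        zones = np.asarray(zones, dtype=np.int8)
        if seconds.shape != zones.shape:
            raise ValueError("seconds and zones must be parallel arrays")
        if seconds.size and (np.any(np.diff(seconds) <= 0)):
            raise ValueError(
                f"hen {self.hen_id} day {day_index}: timestamps not strictly increasing"
            )
        if day_index in self.days:
            raise ValueError(f"hen {self.hen_id}: duplicate day {day_index}")
        self.days[day_index] = (seconds, zones)

    @property
    def day_indices(self) -> list[int]:
        return sorted(self.days)

    @property
    def n_samples(self) -> int:
        return sum(sec.size for sec, _ in self.days.values())

    def iter_samples(self):
        """Yield ``(day_index, second_of_day, zone)`` in order."""
        for d in self.day_indices:
            sec, zon = self.days[d]
            for s, z in zip(sec.tolist(), zon.tolist()):
                yield d, s, z


def henday_label(hen_id: str, day_index: int) -> str:
    """The field's ``henID.dayIndex`` naming, e.g. dataset ``7.3``."""
    return f"{hen_id}.{day_index}"


def split_label(label: str) -> tuple[str, int]:
    hen_id, _, day = label.rpartition(".")
    if not hen_id:
        raise ValueError(f"not a henID.dayIndex label: {label!r}")
    return hen_id, int(day)


@dataclass
class HenDay:
    """One hen's zone-occupancy series over the analysis window."""

    hen_id: str
    day_index: int
    series: np.ndarray  # int8 zone codes, one per second of the window
    window: AnalysisWindow = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=np.int8)
        if self.series.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if self.series.size != self.window.length:
            raise ValueError(
                f"{self.label}: series has {self.series.size} samples, "
                f"window requires {self.window.length}"
            )
        bad = (self.series < 1) | (self.series > N_ZONES)
        if np.any(bad):
            raise ValueError(f"{self.label}: zone codes outside 1..{N_ZONES}")

    @property
    def label(self) -> str:
        return henday_label(self.hen_id, self.day_index)

    @property
    def n_samples(self) -> int:
        return int(self.series.size)


@dataclass(frozen=True)
class HenScore:
    """Per-hen grouping consistency: largest number of this hen's days
    placed in a single group (or predicted as this hen, for a classifier)."""

    hen_id: str
    n_days: int
    count: int

    @property
    def percent(self) -> float:
        return 100.0 * self.count / self.n_days if self.n_days else float("nan")


@dataclass
class GroupingReport:
    """Consistency summary over a flock of hen-days.

    ``overall_pct`` pools days: sum of per-hen counts over total hen-days.
    ``footnotes`` flags merged groups (two hens sharing their best group)
    and hens whose days scatter across several subgroups.
    """

    scores: list[HenScore]
    k: int | None = None
    method: str = ""
    footnotes: list[str] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(s.count for s in self.scores)

    @property
    def total_days(self) -> int:
        return sum(s.n_days for s in self.scores)

    @property
    def overall_pct(self) -> float:
        return 100.0 * self.total_count / self.total_days if self.total_days else float("nan")

    def to_text(self) -> str:
        lines = [f"{'Hen ID':<10}{'days':>6}{'count':>7}{'%':>9}"]
        for s in self.scores:
            lines.append(f"{s.hen_id:<10}{s.n_days:>6}{s.count:>7}{s.percent:>8.0f}%")
        lines.append(
            f"{'Overall':<10}{self.total_days:>6}{self.total_count:>7}"
            f"{self.overall_pct:>8.2f}%"
        )
        if self.k is not None:
            lines.append(f"groups: k = {self.k}")
        for note in self.footnotes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def to_rows(self) -> list[dict]:
        rows = [
            dict(hen_id=s.hen_id, n_days=s.n_days, count=s.count, percent=round(s.percent, 2))
            for s in self.scores
        ]
        rows.append(
            dict(
                hen_id="Overall",
                n_days=self.total_days,
                count=self.total_count,
                percent=round(self.overall_pct, 2),
            )
        )
        return rows


def asdict(obj) -> dict:
    return dataclasses.asdict(obj)
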