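"""Six summary variables per hen-day and the flock-level summary table.

A *visit* is an entry into a zone different from the currently occupied
one; the six variables are visits into each of the five zones plus the
daily total.  The zone occupied at the window's first second is an
occupancy, not a visit, which makes total = sum of the five zone counts
an exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ZONES, ZONE_NAMES, HenDay, split_label

__all__ = [
    "SummaryFeatures",
    "VARIABLES",
    "summarize",
    "feature_table",
    "feature_matrix",
    "flock_summary",
    "percent_of_total",
    "render_flock_summary",
]

VARIABLES: tuple[str, ...] = ("z1", "z2", "z3", "z4", "z5", "total")


@dataclass(frozen=True)
class SummaryFeatures:
    """Visit counts into each zone for one hen-day, plus the total."""

    label: str
    visits: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.visits) != 5 or any(v < 0 for v in self.visits):
            raise ValueError("visits must be five non-negative counts")

    @property
    def total(self) -> int:
        return int(sum(self.visits))

    @property
    def hen_id(self) -> str:
        return split_label(self.label)[0]

    @property
    def day_index(self) -> int:
        return split_label(self.label)[1]

    def as_vector(self) -> np.ndarray:
        """The six-variable vector (z1..z5, total)."""
        return np.array([*self.visits, self.total], dtype=float)


def summarize(henday: HenDay) -> SummaryFeatures:
    """Count entries into each zone within the hen-day's window."""
    series = henday.series
    changed = np.flatnonzero(np.diff(series) != 0) + 1
    entered = series[changed]
    visits = tuple(int(np.count_nonzero(entered == z)) for z in ZONES)
    return SummaryFeatures(label=henday.label, visits=visits)


def feature_table(features: list[SummaryFeatures]) -> pd.DataFrame:
    """Tidy per-hen-day table: label, hen_id, day, z1..z5, total."""
    rows = []
    for f in features:
        rows.append(
            {
                "label": f.label,
                "hen_id": f.hen_id,
                "day": f.day_index,
                **{f"z{z}": f.visits[z - 1] for z in ZONES},
                "total": f.total,
            }
        )
    return pd.DataFrame(rows)


def feature_matrix(features: list[SummaryFeatures]) -> tuple[np.ndarray, list[str]]:
    """(n_hen_days, 6) matrix in VARIABLES order plus row labels."""
    X = np.array([f.as_vector() for f in features], dtype=float)
    return X, [f.label for f in features]


def percent_of_total(zone_mean: float, total_mean: float) -> float:
    """A zone's share of transitions: zone mean / total mean x 100."""
    return 100.0 * zone_mean / total_mean


@dataclass
class FlockSummary:
    """Per-zone mean, standard error and percent-of-total over hen-days.

    SE pools all hen-days (sample SD / sqrt(N)); with a single hen-day the
    SE is reported as NaN (undefined, flagged rather than zero).
    """

    n: int
    mean: dict[str, float]
    se: dict[str, float]
    pct_of_total: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for z in ZONES:
            v = f"z{z}"
            rows.append(
                {
                    "zone": f"{z}: {ZONE_NAMES[z]}",
                    "mean": round(self.mean[v], 2),
                    "se": round(self.se[v], 2),
                    "pct_of_total": round(self.pct_of_total[v], 2),
                }
            )
        rows.append(
            {
                "zone": "Total transitions",
                "mean": round(self.mean["total"], 2),
                "se": round(self.se["total"], 2),
                "pct_of_total": float("nan"),
            }
        )
        return pd.DataFrame(rows)


def flock_summary(features: list[SummaryFeatures]) -> FlockSummary:
    """Flock-level summary of the six variables, pooled over hen-days."""
    if not features:
        raise ValueError("flock_summary requires at least one hen-day")
    X, _ = feature_matrix(features)
    n = X.shape[0]
    mean = X.mean(axis=0)
    if n > 1:
        se = X.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        se = np.full(X.shape[1], np.nan)
    means = dict(zip(VARIABLES, mean.tolist()))
    ses = dict(zip(VARIABLES, se.tolist()))
    pct = {
        f"z{z}": percent_of_total(means[f"z{z}"], means["total"]) for z in ZONES
    }
    return FlockSummary(n=n, mean=means, se=ses, pct_of_total=pct)


def render_flock_summary(summary: FlockSummary) -> str:
    """Aligned text rendering of the flock summary table."""
    df = summary.to_frame()
    lines = [f"{'Zone':<22}{'Mean':>8}{'SE':>8}{'% of total':>12}"]
    for _, r in df.iterrows():
        pct = "-" if np.isnan(r["pct_of_total"]) else f"{r['pct_of_total']:.2f}%"
        se = "-" if np.isnan(r["se"]) else f"{r['se']:.2f}"
        lines.append(f"{r['zone']:<22}{r['mean']:>8.2f}{se:>8}{pct:>12}")
    lines.append(f"(N = {summary.n} hen-days)")
    return "\n".join(lines)
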