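"""Banded Dynamic Time Warping over daily zone series.

The distance between two hen-days is the dynamic-programming optimum over
monotone, boundary-constrained warping paths restricted to a Sakoe-Chiba
band, with a symmetric unit-slope step pattern (diagonal, insertion and
deletion each add one local cost) and no path-length normalisation - the
raw dissimilarities feed Ward clustering directly.

The default local cost is the absolute difference of ordinal zone codes:
zones are numbered along the house's physical/functional axis, so |dz|
approximates locomotor effort.  A 0/1 symbolic mismatch cost is
selectable.  Full-resolution series are 54,000 points; the pipeline
default bins them to 60 s majority zones (900 points) before the
all-pairs matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import HenDay, N_ZONES

logger = logging.getLogger(__name__)

__all__ = [
    "NumericSeries",
    "DTWConfig",
    "DissimilarityMatrix",
    "encode_series",
    "dtw_distance",
    "dtw_matrix",
    "band_width",
    "write_matrix",
    "read_matrix",
]

LOCAL_COSTS = ("abs", "01")


@dataclass(frozen=True)
class NumericSeries:
    """Numeric encoding of a hen-day's zone series."""

    label: str
    values: np.ndarray
    encoding: str = "ordinal"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.ascontiguousarray(self.values, dtype=np.float64)
        )
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("series must be a non-empty 1-D array")

    @property
    def length(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class DTWConfig:
    """Band fraction, local cost and downsampling for the DTW stage."""

    window_frac: float = 0.10
    local_cost: str = "abs"  # "abs" |zone difference|, "01" mismatch
    downsample_s: int = 60  # majority-zone bin width; 1 = off

    def __post_init__(self) -> None:
        if not (0.0 < self.window_frac <= 1.0):
            raise ValueError("window_frac must be in (0, 1]")
        if self.local_cost not in LOCAL_COSTS:
            raise ValueError(f"local_cost must be one of {LOCAL_COSTS}")
        if self.downsample_s < 1:
            raise ValueError("downsample_s must be >= 1")


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise distances among labelled hen-days."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)


# --------------------------------------------------------------------------
# encoding


def encode_series(
    henday: HenDay, encoding: str = "ordinal", downsample_s: int = 1
) -> NumericSeries:
    """Ordinal per-second series, optionally binned to majority zones.

    Within each ``downsample_s`` bin the majority zone wins; ties go to
    the zone appearing earlier in the bin.  A trailing partial bin is
    handled the same way.
    """
    if encoding not in ("ordinal", "symbolic"):
        raise ValueError("encoding must be 'ordinal' or 'symbolic'")
    series = henday.series.astype(np.int64)
    if downsample_s > 1:
        n = series.size
        n_bins = (n + downsample_s - 1) // downsample_s
        padded = np.full(n_bins * downsample_s, 0, dtype=np.int64)
        padded[:n] = series
        binned = padded.reshape(n_bins, downsample_s)
        counts = np.stack(
            [(binned == z).sum(axis=1) for z in range(1, N_ZONES + 1)], axis=1
        )
        best = counts.max(axis=1)
        # tie-break: earliest first occurrence within the bin
        first_pos = np.full((n_bins, N_ZONES), downsample_s, dtype=np.int64)
        for z in range(1, N_ZONES + 1):
            is_z = binned == z
            has = is_z.any(axis=1)
            first_pos[has, z - 1] = np.argmax(is_z[has], axis=1)
        tie_key = np.where(counts == best[:, None], first_pos, downsample_s + 1)
        values = np.argmin(tie_key, axis=1) + 1
    else:
        values = series
    return NumericSeries(
        label=henday.label, values=values.astype(np.float64), encoding=encoding
    )


# --------------------------------------------------------------------------
# banded dynamic programming


def band_width(n: int, m: int, window_frac: float) -> int:
    """Sakoe-Chiba band half-width from the longer series."""
    return int(round(window_frac * max(n, m)))


@njit(cache=False)
def _dtw_banded(a, b, w, absolute_cost):  # pragma: no cover - numba kernel
    n = a.size
    m = b.size
    INF = np.inf
    prev = np.full(m + 1, INF)
    curr = np.full(m + 1, INF)
    prev[0] = 0.0
    for i in range(1, n + 1):
        lo = i - w
        if lo < 1:
            lo = 1
        hi = i + w
        if hi > m:
            hi = m
        curr[:] = INF
        for j in range(lo, hi + 1):
            if absolute_cost:
                d = abs(a[i - 1] - b[j - 1])
            else:
                d = 0.0 if a[i - 1] == b[j - 1] else 1.0
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = d + best
        prev, curr = curr, prev
    return prev[m]


def dtw_distance(
    a: NumericSeries, b: NumericSeries, config: DTWConfig = DTWConfig()
) -> float:
    """Banded DTW distance between two encoded series (unnormalised)."""
    if a.encoding != b.encoding:
        raise ValueError("series encodings differ")
    w = band_width(a.length, b.length, config.window_frac)
    if abs(a.length - b.length) > w:
        raise ValueError(
            f"band width {w} infeasible for length difference "
            f"|{a.length} - {b.length}|"
        )
    dist = float(
        _dtw_banded(a.values, b.values, w, config.local_cost == "abs")
    )
    return dist


def dtw_matrix(
    hendays: list[HenDay], config: DTWConfig = DTWConfig()
) -> DissimilarityMatrix:
    """All-pairs DTW dissimilarities among hen-days."""
    if len(hendays) < 2:
        raise ValueError("need at least two hen-days")
    series = [
        encode_series(hd, encoding="ordinal", downsample_s=config.downsample_s)
        for hd in hendays
    ]
    n = len(series)
    w = band_width(series[0].length, series[0].length, config.window_frac)
    logger.info(
        "DTW matrix: %d series of length %d, band width %d (%.0f%%)",
        n,
        series[0].length,
        w,
        100 * config.window_frac,
    )
    D = np.zeros((n, n))
    n_pairs = n * (n - 1) // 2
    done = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                D[i, j] = D[j, i] = dtw_distance(series[i], series[j], config)
            except ValueError as exc:
                raise ValueError(
                    f"DTW failed for pair ({series[i].label}, {series[j].label}): {exc}"
                ) from exc
            done += 1
        if n > 10 and (i + 1) % 10 == 0:
            logger.info("DTW matrix: %d/%d pairs", done, n_pairs)
    return DissimilarityMatrix(labels=[s.label for s in series], values=D)


# --------------------------------------------------------------------------
# matrix I/O


def write_matrix(matrix: DissimilarityMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels).to_csv(
        path
    )


def read_matrix(path) -> DissimilarityMatrix:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return DissimilarityMatrix(labels=[str(c) for c in df.columns], values=df.to_numpy())
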