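"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithm paths:
brute-force dynamic programs and exhaustive path enumeration for DTW, a
set-based re-agglomeration for Ward linkage, and direct recounting for
transition features.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import hentrack as ht

SEED = 1  # master seed for the reference synthetic flock


# --------------------------------------------------------------------------
# reference flock (session-scoped: shared by feature/classifier tests)


@pytest.fixture(scope="session")
def flock_hendays() -> list[ht.HenDay]:
    profiles = ht.default_profiles(SEED)
    logs = ht.simulate_flock(profiles, n_days=7, master_seed=SEED)
    return ht.build_hen_days(logs)


@pytest.fixture(scope="session")
def flock_features(flock_hendays) -> list[ht.SummaryFeatures]:
    return [ht.summarize(hd) for hd in flock_hendays]


@pytest.fixture(scope="session")
def flock_dtw_matrix(flock_hendays) -> ht.DissimilarityMatrix:
    return ht.dtw_matrix(flock_hendays, ht.DTWConfig(downsample_s=60))


@pytest.fixture()
def mk_henday():
    """Factory: a HenDay from a short zone series (window sized to fit)."""

    def make(series, hen_id="h", day_index=1):
        series = np.asarray(series, dtype=np.int8)
        return ht.HenDay(
            hen_id=hen_id,
            day_index=day_index,
            series=series,
            window=ht.AnalysisWindow(0, series.size),
        )

    return make


# --------------------------------------------------------------------------
# DTW oracles


def dtw_dp_unconstrained(a, b, local="abs") -> float:
    """Plain full-matrix DP, no band; independent of the banded kernel."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    C = np.full((n + 1, m + 1), np.inf)
    C[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = abs(a[i - 1] - b[j - 1]) if local == "abs" else float(a[i - 1] != b[j - 1])
            C[i, j] = d + min(C[i - 1, j - 1], C[i - 1, j], C[i, j - 1])
    return float(C[n, m])


def dtw_enumerate_paths(a, b, local="abs") -> float:
    """Exhaustive minimum over every monotone boundary-to-boundary warping
    path (diagonal / down / right unit steps).  Exponential; lengths <= 8."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size

    def cost(i, j):
        return abs(a[i] - b[j]) if local == "abs" else float(a[i] != b[j])

    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                walk(ni, nj, acc + cost(ni, nj))

    walk(0, 0, cost(0, 0))
    return float(best[0])


# --------------------------------------------------------------------------
# Ward oracle


def ward_naive(D: np.ndarray):
    """Naive re-agglomeration: clusters as frozensets, every inter-cluster
    distance recomputed from scratch each step by recursing on the merge
    history with the Ward Lance-Williams coefficients.  Returns the merge
    heights in order and the final membership at every step.
    """
    n = D.shape[0]
    dist: dict[frozenset, dict[frozenset, float]] = {}
    clusters = [frozenset([i]) for i in range(n)]
    for a, b in itertools.combinations(clusters, 2):
        dist.setdefault(a, {})[b] = D[min(a), min(b)]
        dist.setdefault(b, {})[a] = D[min(a), min(b)]
    heights = []
    merged_sets = []
    order = {c: i for i, c in enumerate(clusters)}  # creation order for ties
    next_ord = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            h = dist[a][b]
            key = (h, min(order[a], order[b]), max(order[a], order[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        h = dist[a][b]
        heights.append(h)
        ab = a | b
        merged_sets.append(ab)
        na, nb = len(a), len(b)
        new_d = {}
        for c in clusters:
            if c in (a, b):
                continue
            nc = len(c)
            tot = na + nb + nc
            new_d[c] = (
                (na + nc) / tot * dist[a][c]
                + (nb + nc) / tot * dist[b][c]
                - nc / tot * h
            )
            dist[c][ab] = new_d[c]
        dist[ab] = new_d
        clusters = [c for c in clusters if c not in (a, b)] + [ab]
        order[ab] = next_ord
        next_ord += 1
    return np.array(heights), merged_sets


def tree_merge_sets(tree) -> list[frozenset]:
    """Leaf-index sets created at each merge step of a LinkageTree."""
    n = tree.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for t in range(n - 1):
        left, right = int(tree.merges[t, 0]), int(tree.merges[t, 1])
        members[n + t] = members[left] | members[right]
        out.append(members[n + t])
    return out


# --------------------------------------------------------------------------
# feature oracle


def recount_transitions(series) -> tuple[dict[int, int], int]:
    """Direct per-sample recount of entries into each zone."""
    visits = {z: 0 for z in range(1, 6)}
    series = list(series)
    for prev, cur in zip(series, series[1:]):
        if cur != prev:
            visits[int(cur)] += 1
    return visits, sum(visits.values())
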