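"""Ward-linkage agglomerative clustering and grouping-consistency scoring.

Implements the ``ward.D`` convention: the Lance-Williams recurrence with
Ward coefficients

    a_i = (n_i + n_k) / (n_i + n_j + n_k)
    a_j = (n_j + n_k) / (n_i + n_j + n_k)
    b   = -n_k / (n_i + n_j + n_k),  g = 0

applied to the dissimilarities exactly as provided (no pre-squaring).
Merges break ties deterministically: lowest height first, then the
lexicographically smallest pair of cluster ids (originals 0..N-1, merged
clusters numbered N, N+1, ... in creation order), which makes trees
reproducible across platforms.

Grouping consistency follows the field's scoring: cut the tree into
n_hens .. n_hens+2 groups, and count, per hen, the largest number of her
days landing in a single group.  Groups may serve several hens (two hens
sharing a best group both score it), flagged by a footnote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import GroupingReport, HenScore, split_label
from .dtw import DissimilarityMatrix
from .features import SummaryFeatures, feature_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageTree",
    "Grouping",
    "feature_distances",
    "ward_linkage",
    "cut_tree",
    "score_grouping",
    "best_grouping",
    "assignment_score",
    "write_linkage",
    "to_newick",
]


@dataclass
class LinkageTree:
    """Merge tree: row t = (left id, right id, height, member count).

    Ids follow the scipy convention: leaves are 0..N-1; the cluster made
    at step t gets id N+t.
    """

    merges: np.ndarray  # (N-1, 4) float
    labels: list[str]

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.labels)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("merge table must have N-1 rows of 4 columns")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class Grouping:
    """A dendrogram cut: hen-day label -> group id (0..k-1)."""

    k: int
    assignment: dict[str, int]

    def __post_init__(self) -> None:
        used = set(self.assignment.values())
        if len(used) != self.k:
            raise ValueError(f"expected exactly {self.k} non-empty groups, got {len(used)}")

    def members(self, group: int) -> list[str]:
        return [lbl for lbl, g in self.assignment.items() if g == group]


# --------------------------------------------------------------------------
# distances on features


def feature_distances(
    features: list[SummaryFeatures], scale: bool = False
) -> DissimilarityMatrix:
    """Euclidean distances on the six variables (z-scored when ``scale``)."""
    if len(features) < 2:
        raise ValueError("need at least two hen-days")
    X, labels = feature_matrix(features)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    D = squareform(pdist(X, metric="euclidean"))
    return DissimilarityMatrix(labels=labels, values=D)


# --------------------------------------------------------------------------
# ward.D linkage


def ward_linkage(D: DissimilarityMatrix) -> LinkageTree:
    """Agglomerate with the Ward Lance-Williams update on raw distances."""
    d = np.array(D.values, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    if np.any(d < 0) or not np.allclose(d, d.T):
        raise ValueError("input must be a symmetric non-negative matrix")

    # active clusters: id -> position in the working matrix
    ids = list(range(n))  # cluster id at each active row
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    work = d.copy()
    np.fill_diagonal(work, np.inf)
    merges = np.zeros((n - 1, 4))
    next_id = n

    for step in range(n - 1):
        m = len(active)
        # find minimal distance; tie-break on smallest (id_i, id_j)
        best = (np.inf, np.inf, np.inf)  # (height, min id, max id)
        bi = bj = -1
        for a in range(m):
            for b in range(a + 1, m):
                h = work[a, b]
                ia, ib = ids[a], ids[b]
                key = (h, min(ia, ib), max(ia, ib))
                if key < best:
                    best = key
                    bi, bj = a, b
        h = work[bi, bj]
        ci, cj = ids[bi], ids[bj]
        ni, nj = sizes[ci], sizes[cj]
        merges[step] = (min(ci, cj), max(ci, cj), h, ni + nj)

        # Lance-Williams update against every other active cluster
        new_row = np.empty(m)
        for a in range(m):
            if a in (bi, bj):
                new_row[a] = np.inf
                continue
            nk = sizes[ids[a]]
            tot = ni + nj + nk
            new_row[a] = (
                (ni + nk) / tot * work[bi, a]
                + (nj + nk) / tot * work[bj, a]
                - nk / tot * h
            )

        # write the merged cluster into slot bi, drop slot bj
        work[bi, :] = new_row
        work[:, bi] = new_row
        work[bi, bi] = np.inf
        keep = [a for a in range(m) if a != bj]
        work = work[np.ix_(keep, keep)]
        ids[bi] = next_id
        sizes[next_id] = ni + nj
        del sizes[ci], sizes[cj]
        ids.pop(bj)
        active.pop()
        next_id += 1

    return LinkageTree(merges=merges, labels=list(D.labels))


def cut_tree(tree: LinkageTree, k: int) -> Grouping:
    """Undo the last k-1 merges: exactly k groups, ids 0..k-1 in leaf order."""
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):  # apply the first n-k merges
        left, right = int(tree.merges[t, 0]), int(tree.merges[t, 1])
        parent[find(left)] = parent[find(right)] = n + t

    roots: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        assignment[tree.labels[leaf]] = roots[r]
    return Grouping(k=k, assignment=assignment)


# --------------------------------------------------------------------------
# consistency scoring


def _hen_of(label: str) -> str:
    return split_label(label)[0]


def score_grouping(
    grouping: Grouping, labels: list[str] | None = None
) -> GroupingReport:
    """Per-hen consistency counts for one dendrogram cut.

    count(hen) = max over groups of the number of that hen's days in the
    group.  Footnotes flag merged groups (two hens sharing a best group)
    and hens whose days scatter over three or more subgroups.
    """
    if labels is None:
        labels = list(grouping.assignment)
    hens = sorted({_hen_of(lbl) for lbl in labels}, key=lambda h: (len(h), h))
    best_group: dict[str, int] = {}
    scores: list[HenScore] = []
    spread: dict[str, int] = {}
    for hen in hens:
        groups: dict[int, int] = {}
        for lbl in labels:
            if _hen_of(lbl) == hen:
                g = grouping.assignment[lbl]
                groups[g] = groups.get(g, 0) + 1
        count = max(groups.values())
        # deterministic best group: highest count, then smallest group id
        best = min(g for g, c in groups.items() if c == count)
        best_group[hen] = best
        spread[hen] = len(groups)
        scores.append(HenScore(hen_id=hen, n_days=sum(groups.values()), count=count))

    footnotes: list[str] = []
    by_group: dict[int, list[str]] = {}
    for hen, g in best_group.items():
        by_group.setdefault(g, []).append(hen)
    for g, members in sorted(by_group.items()):
        if len(members) > 1:
            footnotes.append(f"hens {', '.join(members)} were grouped together")
    for hen in hens:
        if spread[hen] >= 3:
            footnotes.append(
                f"hen {hen}'s days were divided across {spread[hen]} subgroups"
            )
    return GroupingReport(scores=scores, k=grouping.k, footnotes=footnotes)


def best_grouping(
    tree: LinkageTree,
    labels: list[str] | None = None,
    k_range: tuple[int, int] | None = None,
) -> tuple[Grouping, GroupingReport]:
    """Cut at each k in ``k_range`` (default n_hens .. n_hens+2) and keep
    the cut maximising the pooled consistency count; ties -> smallest k."""
    if labels is None:
        labels = list(tree.labels)
    n_hens = len({_hen_of(lbl) for lbl in labels})
    if k_range is None:
        k_range = (n_hens, min(n_hens + 2, tree.n_leaves))
    lo, hi = k_range
    if not (1 <= lo <= hi <= tree.n_leaves):
        raise ValueError(f"invalid k range {k_range}")
    best: tuple[int, int] | None = None  # (-count, k)
    chosen: tuple[Grouping, GroupingReport] | None = None
    for k in range(lo, hi + 1):
        grouping = cut_tree(tree, k)
        report = score_grouping(grouping, labels)
        key = (-report.total_count, k)
        if best is None or key < best:
            best = key
            chosen = (grouping, report)
    assert chosen is not None
    return chosen


def assignment_score(grouping: Grouping, labels: list[str] | None = None) -> GroupingReport:
    """Stricter alternative metric: one-to-one hen-to-group matching by
    maximum-weight bipartite assignment (a group counts for one hen only)."""
    from scipy.optimize import linear_sum_assignment

    if labels is None:
        labels = list(grouping.assignment)
    hens = sorted({_hen_of(lbl) for lbl in labels}, key=lambda h: (len(h), h))
    groups = sorted(set(grouping.assignment.values()))
    M = np.zeros((len(hens), len(groups)))
    days = {h: 0 for h in hens}
    for lbl in labels:
        h = _hen_of(lbl)
        M[hens.index(h), groups.index(grouping.assignment[lbl])] += 1
        days[h] += 1
    rows, cols = linear_sum_assignment(-M)
    counts = {hens[r]: int(M[r, c]) for r, c in zip(rows, cols)}
    scores = [HenScore(h, days[h], counts.get(h, 0)) for h in hens]
    return GroupingReport(scores=scores, k=grouping.k, method="assignment")


# --------------------------------------------------------------------------
# linkage I/O


def write_linkage(tree: LinkageTree, path) -> None:
    """4-column merge table (left, right, height, size) plus leaf labels."""
    with open(path, "w") as fh:
        fh.write("#leaves " + "\t".join(tree.labels) + "\n")
        fh.write("left\tright\theight\tsize\n")
        for left, right, h, size in tree.merges:
            fh.write(f"{int(left)}\t{int(right)}\t{h:.10g}\t{int(size)}\n")


def to_newick(tree: LinkageTree) -> str:
    """Newick rendering with heights as node depths (leaf depth 0)."""
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    text = {i: tree.labels[i].replace(" ", "_") for i in range(n)}
    for t in range(n - 1):
        left, right, h, _ = tree.merges[t]
        left, right = int(left), int(right)
        bl = max(h - height[left], 0.0)
        br = max(h - height[right], 0.0)
        node = n + t
        text[node] = f"({text[left]}:{bl:.6g},{text[right]}:{br:.6g})"
        height[node] = h
    return text[2 * n - 2] + ";"
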