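"""Ward (ward.D) linkage, dendrogram cuts and consistency scoring."""

import shutil
import subprocess

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import hentrack as ht
from hentrack.cluster import (
    assignment_score,
    best_grouping,
    cut_tree,
    feature_distances,
    score_grouping,
    to_newick,
    ward_linkage,
    write_linkage,
)

from conftest import tree_merge_sets, ward_naive


def _dm(points, labels=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    D = squareform(pdist(points))
    labels = labels or [f"h.{i}" for i in range(D.shape[0])]
    return ht.DissimilarityMatrix(labels=labels, values=D)


# --------------------------------------------------------------------------
# linkage


def test_line_example_hand_checked():
    """Points {0, 1, 10} on a line: first merge (0,1) at height 1, then the
    Lance-Williams update gives (2/3)*10 + (2/3)*9 - (1/3)*1 = 37/3."""
    tree = ward_linkage(_dm([0.0, 1.0, 10.0]))
    assert tree.merges[0, 0] == 0 and tree.merges[0, 1] == 1
    assert tree.heights[0] == pytest.approx(1.0)
    assert tree.heights[1] == pytest.approx(37 / 3)


def test_coincident_points_merge_first_at_zero():
    tree = ward_linkage(_dm([5.0, 0.0, 5.0, 9.0]))
    assert tree.heights[0] == 0.0
    assert {int(tree.merges[0, 0]), int(tree.merges[0, 1])} == {0, 2}


def test_heights_monotone_on_random_inputs():
    rng = np.random.default_rng(0)
    for _ in range(10):
        n = int(rng.integers(3, 15))
        tree = ward_linkage(_dm(rng.normal(size=(n, 3))))
        assert np.all(np.diff(tree.heights) >= -1e-10)


def test_matches_naive_reagglomeration_oracle():
    rng = np.random.default_rng(1)
    for trial in range(12):
        n = int(rng.integers(3, 13))
        D = _dm(rng.normal(size=(n, 4)))
        tree = ward_linkage(D)
        heights, merged = ward_naive(D.values)
        np.testing.assert_allclose(tree.heights, heights, rtol=1e-10, atol=1e-12)
        assert tree_merge_sets(tree) == merged


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_matches_r_hclust_ward_d(tmp_path):
    """Cross-check heights and a k=3 cut against R's hclust(method='ward.D')."""
    rng = np.random.default_rng(2)
    D = _dm(rng.normal(size=(9, 3)))
    tree = ward_linkage(D)
    np.savetxt(tmp_path / "d.txt", D.values)
    r = subprocess.run(
        [
            "Rscript",
            "-e",
            f'd<-as.dist(as.matrix(read.table("{tmp_path}/d.txt")));'
            'h<-hclust(d,method="ward.D");'
            'cat(sort(h$height),sep="\\n");cat("--\\n");cat(cutree(h,k=3),sep="\\n")',
        ],
        capture_output=True,
        text=True,
        check=True,
    )
    head, tail = r.stdout.split("--\n")
    r_heights = np.array([float(x) for x in head.split()])
    np.testing.assert_allclose(np.sort(tree.heights), r_heights, rtol=1e-6)
    r_cut = np.array([int(x) for x in tail.split()])
    ours = cut_tree(tree, 3)
    ours_ids = np.array([ours.assignment[lbl] for lbl in tree.labels])
    # same partition up to relabelling
    for g in set(r_cut):
        ours_groups = set(ours_ids[r_cut == g])
        assert len(ours_groups) == 1


def test_invalid_dissimilarity_matrices_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        ht.DissimilarityMatrix(labels=["a", "b"], values=[[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="non-negative"):
        ht.DissimilarityMatrix(labels=["a", "b"], values=[[0.0, -1.0], [-1.0, 0.0]])


# --------------------------------------------------------------------------
# feature distances


def test_feature_distances_basics():
    f0 = ht.SummaryFeatures(label="a.1", visits=(0, 0, 0, 0, 0))
    f1 = ht.SummaryFeatures(label="a.2", visits=(0, 0, 0, 0, 0))
    D = feature_distances([f0, f1])
    assert D.values[0, 1] == 0.0


def test_feature_distances_three_four_five():
    # vectors (0,0,0,0,0,0) and (3,4,0,0,0,0) differ by 3-4-5 in the plane,
    # plus the induced total difference of 7
    f0 = ht.SummaryFeatures(label="a.1", visits=(0, 0, 0, 0, 0))
    f1 = ht.SummaryFeatures(label="a.2", visits=(3, 4, 0, 0, 0))
    D = feature_distances([f0, f1])
    assert D.values[0, 1] == pytest.approx(np.sqrt(3**2 + 4**2 + 7**2))


def test_feature_distances_scaling_unit_variance(flock_features):
    from hentrack.features import feature_matrix

    X, _ = feature_matrix(flock_features)
    sd = X.std(axis=0, ddof=1)
    Z = (X - X.mean(axis=0)) / sd
    D = feature_distances(flock_features, scale=True)
    expected = squareform(pdist(Z))
    np.testing.assert_allclose(D.values, expected, atol=1e-10)
    assert np.allclose(Z.std(axis=0, ddof=1), 1.0)


# --------------------------------------------------------------------------
# cuts


def test_cut_tree_extremes():
    tree = ward_linkage(_dm([0.0, 1.0, 10.0, 11.0]))
    singletons = cut_tree(tree, 4)
    assert len(set(singletons.assignment.values())) == 4
    one = cut_tree(tree, 1)
    assert set(one.assignment.values()) == {0}
    with pytest.raises(ValueError):
        cut_tree(tree, 5)


def test_cut_line_example_k2():
    tree = ward_linkage(_dm([0.0, 1.0, 10.0], labels=["a.1", "a.2", "b.1"]))
    g = cut_tree(tree, 2)
    assert g.assignment["a.1"] == g.assignment["a.2"] != g.assignment["b.1"]


# --------------------------------------------------------------------------
# scoring


def _grouping_from_counts(counts, n_days=7):
    """Build a grouping realising the given per-hen best-group counts:
    count days in the hen's own group, the rest in singleton groups."""
    assignment = {}
    next_group = 0
    hen_groups = {}
    for hen, _ in enumerate(counts):
        hen_groups[str(hen)] = next_group
        next_group += 1
    for hen, c in enumerate(counts):
        for d in range(1, n_days + 1):
            lbl = f"{hen}.{d}"
            if d <= c:
                assignment[lbl] = hen_groups[str(hen)]
            else:
                assignment[lbl] = next_group
                next_group += 1
    k = len(set(assignment.values()))
    return ht.Grouping(k=k, assignment=assignment)


def test_score_counts_best_group_days():
    g = _grouping_from_counts([6], n_days=7)
    rep = score_grouping(g)
    assert rep.scores[0].count == 6
    assert rep.scores[0].percent == pytest.approx(100 * 6 / 7)


def test_two_hens_sharing_a_group_both_score_with_footnote():
    assignment = {f"17.{d}": 0 for d in range(1, 8)}
    assignment.update({f"36.{d}": 0 for d in range(1, 8)})
    assignment["x.1"] = 1
    rep = score_grouping(ht.Grouping(k=2, assignment=assignment))
    by_hen = {s.hen_id: s for s in rep.scores}
    assert by_hen["17"].count == 7 and by_hen["36"].count == 7
    assert any("17" in n and "36" in n and "together" in n for n in rep.footnotes)


def test_days_split_across_subgroups_footnoted():
    assignment = {"39.1": 0, "39.2": 0, "39.3": 1, "39.4": 2}
    rep = score_grouping(ht.Grouping(k=3, assignment=assignment))
    assert any("subgroups" in n for n in rep.footnotes)


def test_score_invariant_to_group_relabelling():
    g = _grouping_from_counts([5, 7, 3])
    perm = {old: new for new, old in enumerate(sorted(set(g.assignment.values()), reverse=True))}
    g2 = ht.Grouping(k=g.k, assignment={l: perm[v] for l, v in g.assignment.items()})
    r1, r2 = score_grouping(g), score_grouping(g2)
    assert [s.count for s in r1.scores] == [s.count for s in r2.scores]
    assert r1.overall_pct == r2.overall_pct


def test_overall_from_published_style_counts():
    counts = [7, 4, 6, 6, 7, 7, 5, 6, 4, 7, 5, 7, 6]
    rep = score_grouping(_grouping_from_counts(counts))
    assert rep.total_count == 77 and rep.total_days == 91
    assert rep.overall_pct == pytest.approx(100 * 77 / 91)
    assert round(rep.overall_pct, 1) == 84.6


def test_assignment_score_shares_nothing():
    assignment = {f"a.{d}": 0 for d in range(1, 8)}
    assignment.update({f"b.{d}": 0 for d in range(1, 8)})
    assignment["c.1"] = 1
    rep = assignment_score(ht.Grouping(k=2, assignment=assignment))
    counts = sorted(s.count for s in rep.scores)
    assert counts == [0, 1, 7]  # the shared group counts for one hen only


# --------------------------------------------------------------------------
# best grouping


def test_best_grouping_singleton_range():
    tree = ward_linkage(_dm([0.0, 1.0, 10.0], labels=["a.1", "a.2", "b.1"]))
    g, rep = best_grouping(tree, k_range=(3, 3))
    assert g.k == 3
    assert all(s.count == 1 for s in rep.scores)


def test_best_grouping_prefers_smallest_k_on_ties():
    # two hens, two coincident days each: k=2 already achieves the maximum
    pts = [0.0, 0.0, 10.0, 10.0]
    tree = ward_linkage(_dm(pts, labels=["a.1", "a.2", "b.1", "b.2"]))
    g, rep = best_grouping(tree, k_range=(2, 4))
    assert g.k == 2
    assert rep.total_count == 4


def test_best_grouping_recovers_separated_hens(flock_features):
    tree = ward_linkage(feature_distances(flock_features))
    g, rep = best_grouping(tree)
    assert 13 <= g.k <= 15
    assert rep.overall_pct >= 85.0


# --------------------------------------------------------------------------
# export


def test_linkage_table_and_newick(tmp_path):
    tree = ward_linkage(_dm([0.0, 1.0, 10.0], labels=["a.1", "a.2", "b.1"]))
    path = tmp_path / "link.tsv"
    write_linkage(tree, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0].startswith("#leaves") and len(lines) == 2 + tree.n_leaves - 1
    nwk = to_newick(tree)
    assert nwk.endswith(";") and "a.1" in nwk and nwk.count("(") == 2
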