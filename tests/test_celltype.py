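import itertools

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from isletpipe import (
    CellRecord,
    ExpressionMatrix,
    ValidationError,
    assign_cell_types,
    detect_doublets,
    hierarchical_cluster,
    select_high_expression_transcripts,
)


def _matrix(genes_levels, cell_ids=None):
    """Build a matrix from {gene: per-cell levels}."""
    genes = list(genes_levels)
    values = np.array([genes_levels[g] for g in genes], dtype=float)
    cell_ids = cell_ids or [f"C{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        [f"T_{g}" for g in genes], {f"T_{g}": g for g in genes}, cell_ids, values
    )


def _records(matrix):
    return [CellRecord(c, "S1", 2_000_000, 0.5) for c in matrix.cell_ids]


# --- high-expression transcript selection ----------------------------------


def test_selection_boundary_inclusive():
    """>=500 RPKM in exactly 2% of 100 cells is included; all-zero excluded."""
    values = np.zeros((2, 100))
    values[0, :2] = 500.0  # exactly ceil(0.02*100)=2 cells at the boundary
    m = ExpressionMatrix(["T1", "T2"], {"T1": "A", "T2": "B"},
                         [f"C{i}" for i in range(100)], values)
    assert select_high_expression_transcripts(m, 500, 0.02) == ["T1"]


def test_selection_rejects_just_below_boundary():
    values = np.zeros((1, 100))
    values[0, 0] = 499.999
    values[0, 1] = 500.0
    m = ExpressionMatrix(["T1"], {"T1": "A"}, [f"C{i}" for i in range(100)], values)
    assert select_high_expression_transcripts(m, 500, 0.02) == []


def test_selection_contains_planted_markers(study_run):
    high = select_high_expression_transcripts(study_run.normalized, 500, 0.02)
    genes = {study_run.normalized.gene_of[t] for t in high}
    assert {"INS", "GCG", "SST", "REG1A"} <= genes


# --- hierarchical clustering ------------------------------------------------


def _naive_average_linkage_cophenetic(points):
    """Brute-force agglomerative average linkage; returns cophenetic matrix."""
    n = len(points)
    D = ssd.squareform(ssd.pdist(points))
    clusters = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = np.mean([D[i, j] for i in a for j in b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in a:
            for j in b:
                coph[i, j] = coph[j, i] = d
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return coph


def test_merge_sequence_matches_brute_force_oracle():
    """5-cell dendrogram equals a brute-force agglomerative implementation."""
    rng = np.random.default_rng(2)
    values = rng.random((4, 5)) * 10  # 4 transcripts x 5 cells
    m = ExpressionMatrix(
        [f"T{i}" for i in range(4)], {f"T{i}": f"G{i}" for i in range(4)},
        [f"C{i}" for i in range(5)], values,
    )
    dendro, _ = hierarchical_cluster(m, "euclidean", "average")
    # oracle runs on the same standardized feature space
    X = values.T
    Xz = (X - X.mean(axis=0)) / X.std(axis=0)
    expected = _naive_average_linkage_cophenetic(Xz)
    observed = ssd.squareform(sch.cophenet(dendro.linkage_matrix))
    np.testing.assert_allclose(observed, expected, rtol=1e-10)


def test_noiseless_groups_recovered_at_k2():
    m = _matrix({"A": [100, 100, 100, 0, 0], "B": [0, 0, 0, 100, 100]})
    _, labels = hierarchical_cluster(m, k=2)
    groups = {}
    for cell, lab in labels.items():
        groups.setdefault(lab, set()).add(cell)
    assert sorted(groups.values(), key=len) == [{"C3", "C4"}, {"C0", "C1", "C2"}]


def test_identical_cells_merge_at_height_zero():
    m = _matrix({"A": [5, 5, 5, 5], "B": [2, 2, 2, 2]})
    dendro, labels = hierarchical_cluster(m, k=1)
    assert np.allclose(dendro.heights, 0.0)
    assert set(labels.values()) == {1}


def test_heights_non_decreasing_and_cut_errors(study_run):
    dendro = study_run.dendrogram
    assert dendro is not None
    assert np.all(np.diff(dendro.heights) >= -1e-12)
    with pytest.raises(ValidationError):
        dendro.cut(10_000)
    newick = dendro.to_newick()
    assert newick.endswith(";") and newick.count("(") == len(dendro.cell_ids) - 1


# --- doublets ---------------------------------------------------------------


def test_dual_marker_cell_flagged():
    m = _matrix({"REG1A": [2000, 0], "INS": [1500, 5000], "GCG": [0, 0], "SST": [0, 0]})
    cells = _records(m)
    retained, excluded, _ = detect_doublets(m, cells, ("REG1A", "GCG", "INS", "SST"), 500)
    assert [c.cell_id for c in excluded] == ["C0"]
    assert [c.cell_id for c in retained] == ["C1"]


def test_fixture_doublets_equal_planted_set(study_run):
    truth = study_run.truth
    flagged = {c.cell_id for c in study_run.cells if c.status == "excluded_doublet"}
    assert flagged == set(truth.cells_of_class("doublet"))


def test_bihormonal_and_doublet_exclusions_disjoint(study_run):
    bihormonal = {c.cell_id for c in study_run.cells if c.status == "excluded_bihormonal"}
    doublet = {c.cell_id for c in study_run.cells if c.status == "excluded_doublet"}
    assert not bihormonal & doublet


# --- typing -----------------------------------------------------------------


def test_marker_maximal_assignment():
    m = _matrix(
        {
            "GCG": [8000, 10, 0, 100],
            "INS": [20, 6000, 0, 200],
            "SST": [0, 0, 0, 50],
            "REG1A": [0, 5, 3000, 100],
        }
    )
    calls, report = assign_cell_types(m, _records(m), min_marker_rpkm=500)
    assert [c.type for c in calls] == ["alpha", "beta", "exocrine", "unassigned"]
    assert report.parameters["type_counts"] == {
        "alpha": 1, "beta": 1, "exocrine": 1, "unassigned": 1,
    }


def test_assignment_permutation_invariant():
    rng = np.random.default_rng(9)
    m = _matrix({g: rng.random(6) * 3000 for g in ("GCG", "INS", "SST", "REG1A")})
    cells = _records(m)
    calls, _ = assign_cell_types(m, cells)
    perm = [cells[i] for i in rng.permutation(6)]
    calls_perm, _ = assign_cell_types(m, perm)
    by_cell = {c.cell_id: c.type for c in calls}
    assert all(by_cell[c.cell_id] == c.type for c in calls_perm)


def test_cluster_marker_concordance_on_fixture(study_run):
    """Cutting the lineage dendrogram at k=4 groups cells by assigned type."""
    dendro = study_run.dendrogram
    labels = dendro.cut(4)
    type_of = {c.cell_id: c.type for c in study_run.type_calls}
    agree = 0
    total = 0
    majority = {}
    for cluster in set(labels.values()):
        members = [c for c, l in labels.items() if l == cluster and c in type_of]
        if not members:
            continue
        types = [type_of[c] for c in members]
        majority[cluster] = max(set(types), key=types.count)
    for cell, cluster in labels.items():
        if cell not in type_of:
            continue
        total += 1
        agree += type_of[cell] == majority[cluster]
    assert agree / total >= 0.99
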