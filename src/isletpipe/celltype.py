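"""Cell-type assignment for post-QC islet cells.

Cells surviving QC are clustered hierarchically on highly expressed
transcripts from a pancreatic lineage panel (per-transcript standardized,
Euclidean distance, average linkage by default), doublets are flagged by
dual expression of the four lineage markers REG1A/GCG/INS/SST above a
threshold, and the remaining cells receive deterministic marker-maximal
type calls: the cell type named by its highest lineage marker (GCG -> alpha,
INS -> beta, SST -> delta, REG1A -> exocrine) when that marker reaches
``min_marker_rpkm``, else ``unassigned``.  The dendrogram provides cluster
context and reporting; the final labels are marker-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .io_core import (
    CellRecord,
    ConfigurationError,
    ExpressionMatrix,
    StageReport,
    ValidationError,
    make_stage_report,
)

__all__ = [
    "CellTypeCall",
    "Dendrogram",
    "DEFAULT_MARKER_TYPE_MAP",
    "select_high_expression_transcripts",
    "hierarchical_cluster",
    "detect_doublets",
    "assign_cell_types",
]

DEFAULT_MARKER_TYPE_MAP: dict[str, str] = {
    "GCG": "alpha",
    "INS": "beta",
    "SST": "delta",
    "REG1A": "exocrine",
}


@dataclass
class CellTypeCall:
    cell_id: str
    type: str  # alpha | beta | delta | exocrine | doublet | unassigned
    basis: dict[str, float] = field(default_factory=dict)  # marker gene -> RPKM
    cluster_id: int | None = None


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over cells.

    ``linkage_matrix`` is in scipy ``linkage`` format (each row: the two
    merged node indices, merge height, merged leaf count); ``leaf_order``
    is the dendrogram's left-to-right leaf ordering as cell ids.
    """

    linkage_matrix: np.ndarray
    cell_ids: list[str]
    leaf_order: list[str]
    linkage: str
    distance: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Flat labels (1..k) by cutting to ``k`` clusters."""
        if k > len(self.cell_ids):
            raise ValidationError(
                f"cannot cut into {k} clusters with {len(self.cell_ids)} cells"
            )
        labels = sch.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.cell_ids, (int(x) for x in labels)))

    def to_newick(self) -> str:
        """Serialize as a Newick tree with merge heights as branch lengths."""
        tree = sch.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.cell_ids[node.id]
            left, right = node.get_left(), node.get_right()
            parts = []
            for child in (left, right):
                length = max(node.dist - (0.0 if child.is_leaf() else child.dist), 0.0)
                parts.append(f"{walk(child)}:{length:g}")
            return f"({','.join(parts)})"

        return walk(tree) + ";"


def select_high_expression_transcripts(
    matrix: ExpressionMatrix,
    min_rpkm: float = 500.0,
    min_cell_fraction: float = 0.02,
) -> list[str]:
    """Transcripts with RPKM >= ``min_rpkm`` in >= ``min_cell_fraction`` of cells.

    Both thresholds are inclusive; the cell-count cut is
    ``ceil(min_cell_fraction * n_cells)``.
    """
    if matrix.n_cells == 0 or matrix.n_transcripts == 0:
        raise ValidationError("cannot select transcripts from an empty matrix")
    need = math.ceil(min_cell_fraction * matrix.n_cells)
    counts = (matrix.values >= min_rpkm).sum(axis=1)
    return [t for t, c in zip(matrix.transcript_ids, counts) if c >= need]


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    distance: str = "euclidean",
    linkage: str = "ward",
    k: int | None = None,
) -> tuple[Dendrogram, dict[str, int] | None]:
    """Agglomerative clustering of cells on per-transcript standardized values.

    Constant transcripts are dropped before standardization.  Deterministic
    given input order.  Returns the dendrogram and, if ``k`` is given, flat
    labels from cutting it into ``k`` clusters.  Ward linkage is the
    default: single/complete/average chain on outlier cells, so low ``k``
    cuts peel off singletons instead of separating the main cell types;
    all scipy linkages remain available.
    """
    if matrix.n_cells < 2:
        raise ValidationError("clustering needs at least 2 cells")
    X = matrix.values.T.astype(float)  # cells x transcripts
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        # all transcripts constant: all pairwise distances zero
        Xz = np.zeros((matrix.n_cells, 1))
    else:
        Xk = X[:, keep]
        Xz = (Xk - Xk.mean(axis=0)) / sd[keep]
    dists = ssd.pdist(Xz, metric=distance)
    Z = sch.linkage(dists, method=linkage)
    leaves = sch.leaves_list(Z)
    dendro = Dendrogram(
        linkage_matrix=Z,
        cell_ids=list(matrix.cell_ids),
        leaf_order=[matrix.cell_ids[i] for i in leaves],
        linkage=linkage,
        distance=distance,
    )
    labels = dendro.cut(k) if k is not None else None
    return dendro, labels


def _marker_levels(
    matrix: ExpressionMatrix, markers: Sequence[str]
) -> dict[str, np.ndarray]:
    levels = {}
    for gene in markers:
        try:
            levels[gene] = matrix.gene_rpkm(gene)
        except ConfigurationError:
            raise ConfigurationError(
                f"lineage marker {gene!r} is absent from the matrix"
            ) from None
    return levels


def detect_doublets(
    matrix: ExpressionMatrix,
    cells: Sequence[CellRecord],
    lineage_markers: Sequence[str] = ("REG1A", "GCG", "INS", "SST"),
    doublet_marker_threshold: float = 500.0,
) -> tuple[list[CellRecord], list[CellRecord], StageReport]:
    """Flag cells co-expressing >= 2 lineage markers above the threshold.

    Dual expression of REG1A/GCG/INS/SST (gene-level summed RPKM, strict
    ``>``) marks a likely co-capture of two cells.
    """
    levels = _marker_levels(matrix, lineage_markers)
    retained, excluded = [], []
    for cell in cells:
        j = matrix.cell_index(cell.cell_id)
        n_high = sum(1 for gene in lineage_markers if levels[gene][j] > doublet_marker_threshold)
        if n_high >= 2:
            cell.exclude("excluded_doublet", "doublet")
            excluded.append(cell)
        else:
            retained.append(cell)
    report = make_stage_report(
        "doublet",
        retained,
        excluded,
        {
            "lineage_markers": list(lineage_markers),
            "doublet_marker_threshold": doublet_marker_threshold,
        },
    )
    return retained, excluded, report


def assign_cell_types(
    matrix: ExpressionMatrix,
    cells: Sequence[CellRecord],
    marker_type_map: Mapping[str, str] | None = None,
    min_marker_rpkm: float = 500.0,
    cluster_labels: Mapping[str, int] | None = None,
) -> tuple[list[CellTypeCall], StageReport]:
    """Marker-maximal type calls for doublet-free cells.

    Each cell's type is the one named by its largest lineage marker
    (``marker_type_map``) when that marker reaches ``min_marker_rpkm``;
    otherwise ``unassigned``.  Ties break by marker map order.
    Permutation-invariant over cell order.
    """
    marker_type_map = dict(marker_type_map or DEFAULT_MARKER_TYPE_MAP)
    markers = list(marker_type_map)
    levels = _marker_levels(matrix, markers)
    calls = []
    type_counts: dict[str, int] = {}
    for cell in cells:
        j = matrix.cell_index(cell.cell_id)
        basis = {gene: float(levels[gene][j]) for gene in markers}
        values = np.array([basis[g] for g in markers])
        best = int(np.argsort(-values, kind="stable")[0])
        if values[best] >= min_marker_rpkm:
            cell_type = marker_type_map[markers[best]]
        else:
            cell_type = "unassigned"
        type_counts[cell_type] = type_counts.get(cell_type, 0) + 1
        calls.append(
            CellTypeCall(
                cell.cell_id,
                cell_type,
                basis,
                cluster_labels.get(cell.cell_id) if cluster_labels else None,
            )
        )
    report = make_stage_report(
        "assign_types",
        list(cells),
        [],
        {"min_marker_rpkm": min_marker_rpkm, "type_counts": dict(sorted(type_counts.items()))},
    )
    return calls, report
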