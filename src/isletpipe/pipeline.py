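"""End-to-end orchestration: QC -> normalize -> type -> DE -> replication.

The stage order is fixed (it defines the ledger semantics): read-depth
filter, exonic-fraction filter, hormone-ratio filter, quantile
normalization of the surviving cells, doublet exclusion, marker-maximal
typing, two-stage differential expression, optional signature replication.
Cell-count conservation — captured = typed + sum of stage exclusions — is
asserted on every run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import celltype, de, normalize, qc, replication
from .io_core import (
    CellRecord,
    ExpressionMatrix,
    LedgerError,
    PipelineConfig,
    StageReport,
    check_cells_match,
    emit_report,
)
from .synthetic_data import FixtureConfig, SyntheticTruth, generate_fixture

__all__ = ["PipelineResult", "RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_sequence: list[str] = field(default_factory=list)
    stage_reports: list[dict] = field(default_factory=list)
    type_counts: dict[str, int] = field(default_factory=dict)
    type_counts_by_subject: dict[str, dict[str, int]] = field(default_factory=dict)
    de_summary: dict = field(default_factory=dict)
    replication_summaries: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


@dataclass
class PipelineResult:
    manifest: RunManifest
    reports: list[StageReport]
    normalized: ExpressionMatrix  # post-QC cells, quantile-normalized
    hormone_calls: list[qc.HormoneCall]
    dendrogram: celltype.Dendrogram | None
    type_calls: list[celltype.CellTypeCall]
    de_results: list[de.DETestResult]
    replication_results: dict[str, list[replication.ReplicationResult]]
    truth: SyntheticTruth | None = None
    cells: list[CellRecord] = field(default_factory=list)

    def typed_cells(self) -> list[celltype.CellTypeCall]:
        return [c for c in self.type_calls if c.type != "unassigned"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig | None = None,
    matrix: ExpressionMatrix | None = None,
    cells: Sequence[CellRecord] | None = None,
    simulate: FixtureConfig | None = None,
    signatures: Sequence[replication.SignatureSet] = (),
    run_de: bool = True,
    cluster_k: int = 4,
) -> PipelineResult:
    """Run the full pipeline on user data or on a simulated capture.

    Exactly one of ``(matrix, cells)`` or ``simulate`` must be provided.
    Deterministic given the simulation seed; the analysis stages consume no
    randomness.
    """
    cfg = config or PipelineConfig()
    truth = None
    if simulate is not None:
        if matrix is not None or cells is not None:
            raise ValueError("pass either simulate= or (matrix=, cells=), not both")
        matrix, cells, truth = generate_fixture(simulate)
    if matrix is None or cells is None:
        raise ValueError("matrix and cells are required unless simulate= is given")
    cells = list(cells)
    check_cells_match(matrix, cells)
    n_captured = len(cells)
    reports: list[StageReport] = []

    # --- QC on metadata ---------------------------------------------------
    retained, _, rep = qc.filter_low_reads(cells, cfg.min_reads)
    reports.append(rep)
    retained, _, rep = qc.filter_low_exonic(retained, cfg.min_exonic_fraction)
    reports.append(rep)

    # --- hormone-ratio QC on raw RPKM -------------------------------------
    qc_matrix = matrix.subset_cells([c.cell_id for c in retained])
    retained, _, rep, hormone_calls = qc.filter_bihormonal(
        qc_matrix, retained, cfg.hormone_ratio_max, cfg.hormone_panel
    )
    reports.append(rep)

    # --- normalization of the post-QC matrix ------------------------------
    raw_post_qc = matrix.subset_cells([c.cell_id for c in retained])
    normalized = normalize.quantile_normalize(raw_post_qc)
    threshold_matrix = normalized if cfg.thresholds_on == "normalized" else raw_post_qc

    # --- clustering on highly expressed lineage-panel transcripts ---------
    high = celltype.select_high_expression_transcripts(
        threshold_matrix, cfg.hvt_min_rpkm, cfg.hvt_min_cell_fraction
    )
    panel_genes = set(cfg.lineage_panel)
    panel_transcripts = [t for t in high if threshold_matrix.gene_of[t] in panel_genes]
    dendrogram = None
    if panel_transcripts and len(retained) >= 2:
        dendrogram, _ = celltype.hierarchical_cluster(
            normalized.subset_transcripts(panel_transcripts),
            distance=cfg.clustering_distance,
            linkage=cfg.clustering_linkage,
        )

    # --- doublet exclusion and typing -------------------------------------
    doublet_markers = tuple(cfg.marker_type_map)
    retained, _, rep = celltype.detect_doublets(
        threshold_matrix, retained, doublet_markers, cfg.doublet_marker_threshold
    )
    reports.append(rep)
    cluster_labels = (
        dendrogram.cut(min(cluster_k, len(retained))) if dendrogram is not None else None
    )
    type_matrix = threshold_matrix.subset_cells([c.cell_id for c in retained])
    type_calls, rep = celltype.assign_cell_types(
        type_matrix, retained, cfg.marker_type_map, cfg.min_marker_rpkm, cluster_labels
    )
    reports.append(rep)
    for cell in retained:
        cell.status = "retained"

    # --- global ledger conservation ---------------------------------------
    n_excluded = sum(r.n_excluded for r in reports)
    if n_captured != len(retained) + n_excluded:
        raise LedgerError(
            f"conservation violated: captured {n_captured} != retained "
            f"{len(retained)} + excluded {n_excluded}"
        )

    type_counts: dict[str, int] = {}
    by_subject: dict[str, dict[str, int]] = {}
    subject_of = {c.cell_id: c.subject_id for c in cells}
    for call in type_calls:
        type_counts[call.type] = type_counts.get(call.type, 0) + 1
        sub = by_subject.setdefault(subject_of[call.cell_id], {})
        sub[call.type] = sub.get(call.type, 0) + 1

    # --- two-stage DE ------------------------------------------------------
    de_results: list[de.DETestResult] = []
    de_summary: dict = {}
    if run_de:
        de_results, de_report = de.two_stage_de(
            normalized,
            type_calls,
            subject_of,
            cfg.discovery_subjects,
            cfg.validation_subjects,
            cfg,
        )
        reports.append(de_report)
        de_summary = de_report.parameters

    # --- signature replication ---------------------------------------------
    replication_results: dict[str, list[replication.ReplicationResult]] = {}
    replication_summaries: dict[str, dict[str, int]] = {}
    for signature in signatures:
        results, summary = replication.replicate_signature(
            normalized, type_calls, signature, cfg
        )
        replication_results[signature.name] = results
        replication_summaries[signature.name] = summary

    manifest = RunManifest(
        config=cfg.to_dict(),
        seed=simulate.seed if simulate is not None else cfg.seed,
        stage_sequence=[r.stage for r in reports],
        stage_reports=[r.to_dict() for r in reports],
        type_counts=dict(sorted(type_counts.items())),
        type_counts_by_subject={k: dict(sorted(v.items())) for k, v in sorted(by_subject.items())},
        de_summary=de_summary,
        replication_summaries=replication_summaries,
    )
    return PipelineResult(
        manifest=manifest,
        reports=reports,
        normalized=normalized,
        hormone_calls=hormone_calls,
        dendrogram=dendrogram,
        type_calls=type_calls,
        de_results=de_results,
        replication_results=replication_results,
        truth=truth,
        cells=cells,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write manifest, ledger, type calls and DE table to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["manifest"] = result.manifest.to_json(out / "manifest.json")
    paths["ledger"] = emit_report(result.reports, out / "ledger.json")
    type_lines = ["cell_id\ttype\tcluster_id"]
    for call in result.type_calls:
        type_lines.append(f"{call.cell_id}\t{call.type}\t{call.cluster_id if call.cluster_id is not None else ''}")
    (out / "cell_types.tsv").write_text("\n".join(type_lines) + "\n")
    paths["cell_types"] = out / "cell_types.tsv"
    de_lines = [
        "transcript_id\tgene\tdirection\tverdict\t"
        "discovery_adj_p\tdiscovery_fc\tvalidation_adj_p\tvalidation_fc"
    ]
    for r in result.de_results:
        disc = r.discovery
        val = r.validation
        de_lines.append(
            "\t".join(
                [
                    r.transcript_id,
                    r.gene,
                    r.direction or "",
                    r.verdict,
                    f"{disc.adjusted_p:.6g}" if disc else "",
                    f"{disc.signed_fc:.6g}" if disc else "",
                    f"{val.adjusted_p:.6g}" if val else "",
                    f"{val.signed_fc:.6g}" if val else "",
                ]
            )
        )
    (out / "de_results.tsv").write_text("\n".join(de_lines) + "\n")
    paths["de_results"] = out / "de_results.tsv"
    if result.dendrogram is not None:
        (out / "dendrogram.nwk").write_text(result.dendrogram.to_newick() + "\n")
        paths["dendrogram"] = out / "dendrogram.nwk"
    for name, results in result.replication_results.items():
        lines = ["gene\ttranscript\tclaimed\tclass\traw_p\tadj_p\tfold_change"]
        for r in results:
            lines.append(
                "\t".join(
                    [
                        r.entry.gene,
                        r.transcript_tested or "",
                        r.entry.claimed_direction,
                        r.class_,
                        f"{r.raw_p:.6g}" if r.raw_p is not None else "",
                        f"{r.adjusted_p:.6g}" if r.adjusted_p is not None else "",
                        f"{r.signed_fc:.6g}" if r.signed_fc is not None else "",
                    ]
                )
            )
        (out / f"replication_{name}.tsv").write_text("\n".join(lines) + "\n")
        paths[f"replication_{name}"] = out / f"replication_{name}.tsv"
    return paths
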