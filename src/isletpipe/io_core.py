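"""Core domain types and file I/O for the islet scRNA-seq pipeline.

The pipeline operates on a cells x transcripts RPKM matrix (transcript-level
rows, each mapped to a gene symbol) plus a per-cell metadata table carrying
the subject of origin, the total sequenced reads and the fraction of reads
aligned to exons.  Transcripts -- not genes -- are the unit of analysis
throughout; gene-level values are derived views (a gene's RPKM in a cell is
the sum over its transcripts).

Supported on-disk formats:

* dense TSV: ``transcript_id<TAB>gene<TAB><cell1><TAB><cell2>...`` with one
  row per transcript;
* Matrix Market coordinate (``.mtx``) with two sidecar files,
  ``<path>.rows`` (``transcript_id<TAB>gene`` per line) and ``<path>.cols``
  (one cell id per line);
* metadata TSV with columns ``cell_id, subject_id, total_reads,
  exonic_fraction``;
* JSON stage-report ledgers.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "IsletPipeError",
    "ValidationError",
    "SchemaError",
    "LedgerError",
    "ConfigurationError",
    "EXCLUDED_STATUSES",
    "ExpressionMatrix",
    "CellRecord",
    "PipelineConfig",
    "StageReport",
    "read_matrix",
    "write_matrix",
    "read_cell_metadata",
    "write_cell_metadata",
    "emit_report",
]


class IsletPipeError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(IsletPipeError):
    """A value violates a domain invariant (negative RPKM, bad fraction...)."""


class SchemaError(IsletPipeError):
    """A file does not match the expected dialect (missing column, ragged row)."""


class LedgerError(IsletPipeError):
    """A stage report ledger is internally inconsistent."""


class ConfigurationError(IsletPipeError):
    """A configured gene or parameter cannot be resolved against the data."""


#: cell statuses that mark an exclusion; once set they are never reverted
EXCLUDED_STATUSES = frozenset(
    {
        "excluded_low_reads",
        "excluded_low_exonic",
        "excluded_bihormonal",
        "excluded_doublet",
    }
)

_VALID_STATUSES = EXCLUDED_STATUSES | {"unfiltered", "retained"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Transcripts x cells matrix of non-negative RPKM values.

    Parameters
    ----------
    transcript_ids :
        Ordered, unique transcript accessions (rows).
    gene_of :
        Map transcript id -> gene symbol.  Several transcripts may share a
        gene (e.g. the two INS transcripts), but every transcript has exactly
        one gene.
    cell_ids :
        Ordered, unique cell identifiers (columns).
    values :
        ``(n_transcripts, n_cells)`` array of finite values >= 0.
    """

    transcript_ids: list[str]
    gene_of: dict[str, str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        _check_unique(self.transcript_ids, "transcript_id")
        _check_unique(self.cell_ids, "cell_id")
        if self.values.shape != (len(self.transcript_ids), len(self.cell_ids)):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {len(self.cell_ids)} cells"
            )
        missing = [t for t in self.transcript_ids if t not in self.gene_of]
        if missing:
            raise ValidationError(f"transcripts without gene symbol: {missing[:5]}")
        if self.values.size:
            if not np.all(np.isfinite(self.values)):
                i, j = np.argwhere(~np.isfinite(self.values))[0]
                raise ValidationError(
                    f"non-finite value at transcript {self.transcript_ids[i]!r}, "
                    f"cell {self.cell_ids[j]!r}"
                )
            if (self.values < 0).any():
                i, j = np.argwhere(self.values < 0)[0]
                raise ValidationError(
                    f"negative value {self.values[i, j]} at transcript "
                    f"{self.transcript_ids[i]!r}, cell {self.cell_ids[j]!r}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_index(self, cell_id: str) -> int:
        try:
            return self._cell_pos[cell_id]
        except AttributeError:
            self._cell_pos = {c: i for i, c in enumerate(self.cell_ids)}
            return self._cell_pos[cell_id]

    def genes(self) -> list[str]:
        """Distinct gene symbols in transcript order of first appearance."""
        seen: dict[str, None] = {}
        for t in self.transcript_ids:
            seen.setdefault(self.gene_of[t], None)
        return list(seen)

    def gene_rpkm(self, gene: str) -> np.ndarray:
        """Summed RPKM of all transcripts of ``gene``, one value per cell."""
        rows = [i for i, t in enumerate(self.transcript_ids) if self.gene_of[t] == gene]
        if not rows:
            raise ConfigurationError(f"gene {gene!r} is absent from the matrix")
        return self.values[rows].sum(axis=0)

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.cell_index(c) for c in cell_ids]
        return ExpressionMatrix(
            list(self.transcript_ids),
            dict(self.gene_of),
            list(cell_ids),
            self.values[:, idx].copy(),
        )

    def subset_transcripts(self, transcript_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {t: i for i, t in enumerate(self.transcript_ids)}
        idx = [pos[t] for t in transcript_ids]
        return ExpressionMatrix(
            list(transcript_ids),
            {t: self.gene_of[t] for t in transcript_ids},
            list(self.cell_ids),
            self.values[idx].copy(),
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.transcript_ids), dict(self.gene_of), list(self.cell_ids), values
        )

    def __eq__(self, other: object) -> bool:  # value equality incl. orderings
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.transcript_ids == other.transcript_ids
            and self.cell_ids == other.cell_ids
            and self.gene_of == other.gene_of
            and self.values.shape == other.values.shape
            and np.allclose(self.values, other.values, rtol=1e-9, atol=0.0)
        )


@dataclass
class CellRecord:
    """Per-cell metadata plus evolving QC status."""

    cell_id: str
    subject_id: str
    total_reads: int
    exonic_fraction: float
    status: str = "unfiltered"
    exclusion_stage: str | None = None

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValidationError(
                f"cell {self.cell_id!r}: negative total_reads {self.total_reads}"
            )
        if not 0.0 <= self.exonic_fraction <= 1.0:
            raise ValidationError(
                f"cell {self.cell_id!r}: exonic_fraction {self.exonic_fraction} "
                "outside [0, 1]"
            )
        if self.status not in _VALID_STATUSES:
            raise ValidationError(f"unknown status {self.status!r}")

    @property
    def is_excluded(self) -> bool:
        return self.status in EXCLUDED_STATUSES

    def exclude(self, status: str, stage: str) -> None:
        """Mark the cell excluded; exclusion is monotone (never reverted)."""
        if status not in EXCLUDED_STATUSES:
            raise ValidationError(f"{status!r} is not an exclusion status")
        if self.is_excluded:
            raise ValidationError(
                f"cell {self.cell_id!r} already excluded at stage "
                f"{self.exclusion_stage!r}; exclusion is monotone"
            )
        self.status = status
        self.exclusion_stage = stage


@dataclass
class PipelineConfig:
    """All numeric thresholds and panels used by the pipeline.

    Defaults follow the study design this package emulates: cells with fewer
    than one million reads or under 30% exonic alignment are dropped, cells
    whose secondary islet hormone exceeds 10% of the primary are treated as
    bi-hormonal artifacts, "highly expressed" means RPKM >= 500 in >= 2% of
    cells, and the differential-expression prevalence filter keeps
    transcripts with RPKM > 50 in at least 25% of cells (stringent variants
    42% / 47%).
    """

    min_reads: int = 1_000_000
    min_exonic_fraction: float = 0.30
    hormone_ratio_max: float = 0.10
    hormone_panel: tuple[str, ...] = ("INS", "GCG", "SST")
    hvt_min_rpkm: float = 500.0
    hvt_min_cell_fraction: float = 0.02
    de_min_rpkm: float = 50.0
    de_min_cell_fraction: float = 0.25
    alpha: float = 0.05
    fc_threshold: float = 1.5
    lineage_panel: tuple[str, ...] = (
        "INS",
        "GCG",
        "SST",
        "PPY",
        "GHRL",
        "REG1A",
        "PDX1",
        "ARX",
        "MAFA",
        "MAFB",
        "NKX6-1",
        "NEUROG3",
        "PTF1A",
        "CPA1",
    )
    doublet_marker_threshold: float = 500.0
    min_marker_rpkm: float = 500.0
    marker_type_map: dict[str, str] = field(
        default_factory=lambda: {
            "GCG": "alpha",
            "INS": "beta",
            "SST": "delta",
            "REG1A": "exocrine",
        }
    )
    clustering_distance: str = "euclidean"
    clustering_linkage: str = "ward"
    thresholds_on: str = "normalized"  # or "raw"
    log2_de: bool = False
    pooled_validation_correction: bool = False
    discovery_subjects: tuple[str, ...] = ("S1", "S2")
    validation_subjects: tuple[str, ...] = ("S3",)
    seed: int = 0

    def __post_init__(self) -> None:
        self.hormone_panel = tuple(self.hormone_panel)
        self.lineage_panel = tuple(self.lineage_panel)
        self.discovery_subjects = tuple(self.discovery_subjects)
        self.validation_subjects = tuple(self.validation_subjects)
        self.validate()

    def validate(self) -> None:
        positives = {
            "min_reads": self.min_reads,
            "min_exonic_fraction": self.min_exonic_fraction,
            "hormone_ratio_max": self.hormone_ratio_max,
            "hvt_min_rpkm": self.hvt_min_rpkm,
            "de_min_rpkm": self.de_min_rpkm,
            "alpha": self.alpha,
            "fc_threshold": self.fc_threshold,
            "doublet_marker_threshold": self.doublet_marker_threshold,
            "min_marker_rpkm": self.min_marker_rpkm,
        }
        for name, value in positives.items():
            if not value > 0:
                raise ValidationError(f"{name} must be strictly positive, got {value}")
        for name, value in (
            ("hvt_min_cell_fraction", self.hvt_min_cell_fraction),
            ("de_min_cell_fraction", self.de_min_cell_fraction),
            ("min_exonic_fraction", self.min_exonic_fraction),
        ):
            if not 0 < value <= 1:
                raise ValidationError(f"{name} must lie in (0, 1], got {value}")
        if self.thresholds_on not in ("normalized", "raw"):
            raise ValidationError(
                f"thresholds_on must be 'normalized' or 'raw', got {self.thresholds_on!r}"
            )

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, Mapping):
            raise SchemaError(f"config file {path} is not a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("hormone_panel", "lineage_panel", "discovery_subjects", "validation_subjects"):
            out[key] = list(out[key])
        return out

    def replace(self, **changes) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class StageReport:
    """Ledger entry for one pipeline stage: input = excluded + retained."""

    stage: str
    n_input: int
    n_excluded: int
    n_retained: int
    per_subject: dict[str, dict[str, int]] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_input != self.n_excluded + self.n_retained:
            raise LedgerError(
                f"stage {self.stage!r}: input {self.n_input} != excluded "
                f"{self.n_excluded} + retained {self.n_retained}"
            )
        if self.per_subject:
            for key, total in (
                ("input", self.n_input),
                ("excluded", self.n_excluded),
                ("retained", self.n_retained),
            ):
                s = sum(v[key] for v in self.per_subject.values())
                if s != total:
                    raise LedgerError(
                        f"stage {self.stage!r}: per-subject {key} sums to {s}, "
                        f"expected {total}"
                    )

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_input": self.n_input,
            "n_excluded": self.n_excluded,
            "n_retained": self.n_retained,
            "per_subject": self.per_subject,
            "parameters": self.parameters,
        }


def make_stage_report(
    stage: str,
    retained: Sequence[CellRecord],
    excluded: Sequence[CellRecord],
    parameters: Mapping | None = None,
) -> StageReport:
    """Build a per-subject stage ledger from a cell partition."""
    per_subject: dict[str, dict[str, int]] = {}
    for rec, key in [(r, "retained") for r in retained] + [(r, "excluded") for r in excluded]:
        entry = per_subject.setdefault(rec.subject_id, {"input": 0, "excluded": 0, "retained": 0})
        entry["input"] += 1
        entry[key] += 1
    report = StageReport(
        stage=stage,
        n_input=len(retained) + len(excluded),
        n_excluded=len(excluded),
        n_retained=len(retained),
        per_subject=dict(sorted(per_subject.items())),
        parameters=dict(parameters or {}),
    )
    report.validate()
    return report


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

_TSV_HEADER_PREFIX = ("transcript_id", "gene")


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} {x!r}")
        seen.add(x)


def read_matrix(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from ``tsv`` or ``mtx_triplet`` format."""
    path = Path(path)
    if format == "tsv":
        return _read_matrix_tsv(path)
    if format in ("mtx", "mtx_triplet"):
        return _read_matrix_mtx(path)
    raise SchemaError(f"unknown matrix format {format!r}")


def _read_matrix_tsv(path: Path) -> ExpressionMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        if tuple(header[:2]) != _TSV_HEADER_PREFIX:
            raise SchemaError(
                f"{path}: header must start with {_TSV_HEADER_PREFIX}, got {header[:2]}"
            )
        cell_ids = header[2:]
        _check_unique(cell_ids, "cell_id")
        transcript_ids: list[str] = []
        gene_of: dict[str, str] = {}
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise SchemaError(
                    f"{path}: line {lineno} has {len(row)} fields, expected {len(header)}"
                )
            tid, gene = row[0], row[1]
            if tid in gene_of:
                raise ValidationError(f"{path}: duplicate transcript_id {tid!r}")
            gene_of[tid] = gene
            transcript_ids.append(tid)
            try:
                values = [float(x) for x in row[2:]]
            except ValueError as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from None
            for j, v in enumerate(values):
                if not math.isfinite(v) or v < 0:
                    raise ValidationError(
                        f"{path}: invalid value {v} at transcript {tid!r}, "
                        f"cell {cell_ids[j]!r}"
                    )
            rows.append(values)
    values_arr = (
        np.array(rows, dtype=float)
        if rows
        else np.empty((0, len(cell_ids)), dtype=float)
    )
    return ExpressionMatrix(transcript_ids, gene_of, cell_ids, values_arr)


def _read_matrix_mtx(path: Path) -> ExpressionMatrix:
    import scipy.io

    path = Path(path)
    rows_path = path.with_name(path.name + ".rows")
    cols_path = path.with_name(path.name + ".cols")
    for side in (rows_path, cols_path):
        if not side.exists():
            raise SchemaError(f"missing sidecar file {side}")
    transcript_ids: list[str] = []
    gene_of: dict[str, str] = {}
    for lineno, line in enumerate(rows_path.read_text().splitlines(), start=1):
        parts = line.split("\t")
        if len(parts) != 2:
            raise SchemaError(f"{rows_path}: line {lineno}: expected 'transcript<TAB>gene'")
        tid, gene = parts
        if tid in gene_of:
            raise ValidationError(f"{rows_path}: duplicate transcript_id {tid!r}")
        transcript_ids.append(tid)
        gene_of[tid] = gene
    cell_ids = cols_path.read_text().splitlines()
    _check_unique(cell_ids, "cell_id")
    mat = scipy.io.mmread(str(path))
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    if dense.shape != (len(transcript_ids), len(cell_ids)):
        raise SchemaError(
            f"{path}: matrix shape {dense.shape} does not match sidecars "
            f"({len(transcript_ids)} x {len(cell_ids)})"
        )
    if dense.size and (dense < 0).any():
        i, j = np.argwhere(dense < 0)[0]
        raise ValidationError(
            f"{path}: negative value {dense[i, j]} at row {i + 1}, column {j + 1} "
            f"(transcript {transcript_ids[i]!r}, cell {cell_ids[j]!r})"
        )
    return ExpressionMatrix(transcript_ids, gene_of, cell_ids, dense)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> Path:
    """Write a matrix; ``read_matrix(write_matrix(m)) == m`` up to >= 9
    significant digits of value formatting."""
    path = Path(path)
    matrix.validate()
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(list(_TSV_HEADER_PREFIX) + list(matrix.cell_ids))
            for i, tid in enumerate(matrix.transcript_ids):
                writer.writerow(
                    [tid, matrix.gene_of[tid]]
                    + [format_value(v) for v in matrix.values[i]]
                )
        return path
    if format in ("mtx", "mtx_triplet"):
        import scipy.io
        import scipy.sparse

        scipy.io.mmwrite(
            str(path), scipy.sparse.coo_matrix(matrix.values), precision=12
        )
        # mmwrite appends .mtx if missing; normalise to the requested name
        written = path if path.exists() else path.with_name(path.name + ".mtx")
        if written != path:
            written.rename(path)
        path.with_name(path.name + ".rows").write_text(
            "".join(f"{t}\t{matrix.gene_of[t]}\n" for t in matrix.transcript_ids)
        )
        path.with_name(path.name + ".cols").write_text(
            "".join(f"{c}\n" for c in matrix.cell_ids)
        )
        return path
    raise SchemaError(f"unknown matrix format {format!r}")


def format_value(v: float) -> str:
    """Locale-independent decimal formatting at 12 significant digits."""
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return f"{v:.12g}"


# ---------------------------------------------------------------------------
# metadata and reports
# ---------------------------------------------------------------------------

_META_COLUMNS = ("cell_id", "subject_id", "total_reads", "exonic_fraction")


def read_cell_metadata(path: str | Path) -> list[CellRecord]:
    """Read the per-cell metadata TSV; all records start ``unfiltered``."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_META_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"{path}: missing metadata columns {sorted(missing)}")
        records = []
        for row in reader:
            records.append(
                CellRecord(
                    cell_id=row["cell_id"],
                    subject_id=row["subject_id"],
                    total_reads=int(row["total_reads"]),
                    exonic_fraction=float(row["exonic_fraction"]),
                )
            )
    _check_unique((r.cell_id for r in records), "cell_id")
    return records


def write_cell_metadata(records: Sequence[CellRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_META_COLUMNS)
        for r in records:
            writer.writerow(
                [r.cell_id, r.subject_id, r.total_reads, format_value(r.exonic_fraction)]
            )
    return path


def check_cells_match(matrix: ExpressionMatrix, records: Sequence[CellRecord]) -> None:
    """Require metadata and matrix to describe the same cell set."""
    meta = {r.cell_id for r in records}
    mat = set(matrix.cell_ids)
    if meta != mat:
        diff = sorted(meta.symmetric_difference(mat))
        raise ValidationError(
            f"metadata and matrix cell sets differ; symmetric difference: {diff}"
        )


def emit_report(
    reports: Sequence[StageReport],
    path: str | Path,
    extra: Mapping | None = None,
) -> Path:
    """Serialize the full stage ledger to JSON, validating it first."""
    for report in reports:
        report.validate()
    doc = {"stages": [r.to_dict() for r in reports]}
    if extra:
        doc.update(extra)
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")
    return path
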