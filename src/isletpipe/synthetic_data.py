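"""Synthetic islet scRNA-seq fixtures with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes at the RPKM level: mono-hormonal endocrine cells dominated by one of
INS/GCG/SST, REG1A-high exocrine cells, capture artifacts (cells with too few
reads, cells with a low exonic alignment fraction, bi-hormonal cells whose
secondary hormone exceeds the QC ratio, and REG1A+hormone doublets), plus a
background "program" of transcripts shared by all cells into which
differentially expressed transcripts between alpha- and beta-cells are
planted at configurable fold changes.

``default_study_config`` reproduces the emulated study's cell ledger: a
448-cell capture from three subjects (138/84/226) that, after the three QC
filters and doublet exclusion, yields exactly 118 alpha, 105 beta, 6 delta
and 47 exocrine cells.

Expression noise is multiplicative lognormal with optional dropout; a margin
parameter keeps every planted cell's hormone ratio away from the QC
threshold so filter decisions on fixtures are deterministic under noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_core import (
    CellRecord,
    ExpressionMatrix,
    ValidationError,
    write_cell_metadata,
    write_matrix,
)

__all__ = [
    "FixtureConfig",
    "SyntheticTruth",
    "CELL_CLASSES",
    "default_study_config",
    "generate_fixture",
    "write_truth",
]

#: planted cell classes, in generation order
CELL_CLASSES = (
    "alpha",
    "beta",
    "delta",
    "exocrine",
    "doublet",
    "bihormonal",
    "low_read",
    "low_exonic",
)

# hormone/marker transcripts; INS is split over two transcripts sharing one
# gene symbol, mirroring real RefSeq annotation
HORMONE_TRANSCRIPTS: dict[str, tuple[tuple[str, float], ...]] = {
    "INS": (("NM_000207", 0.9), ("NM_001185097", 0.1)),
    "GCG": (("NM_002054", 1.0),),
    "SST": (("NM_001048", 1.0),),
}
REG1A_TRANSCRIPT = ("NM_002909", "REG1A")

# modest type-specific transcription-factor programs on the lineage panel
TF_PROGRAMS: dict[str, dict[str, float]] = {
    "alpha": {"ARX": 300.0, "MAFB": 250.0},
    "beta": {"PDX1": 300.0, "MAFA": 250.0, "NKX6-1": 250.0},
    "delta": {"MAFB": 150.0},
    "exocrine": {"PTF1A": 300.0, "CPA1": 400.0},
}
TF_TRANSCRIPTS: dict[str, str] = {
    "ARX": "NM_139058",
    "MAFB": "NM_005461",
    "PDX1": "NM_000209",
    "MAFA": "NM_201589",
    "NKX6-1": "NM_006168",
    "PTF1A": "NM_178161",
    "CPA1": "NM_001868",
}

#: primary hormone of each endocrine class
CLASS_HORMONE = {"alpha": "GCG", "beta": "INS", "delta": "SST"}


@dataclass
class FixtureConfig:
    """Parameters of one synthetic capture.

    ``class_counts`` maps each planted class to per-subject cell counts
    (same length as ``subjects``); each subject's class counts must sum to
    its capture count.
    """

    subjects: tuple[str, ...] = ("S1", "S2", "S3")
    captures: tuple[int, ...] = (138, 84, 226)
    class_counts: dict[str, tuple[int, ...]] = field(default_factory=dict)
    marker_level: float = 5000.0
    background_level: float = 1.0
    n_de_per_direction: int = 10
    de_fold: float = 8.0
    de_base_level: float = 200.0
    n_null: int = 100
    sigma: float = 0.4
    dropout: float = 0.1
    margin: float = 0.02
    hormone_ratio_max: float = 0.10
    min_reads: int = 1_000_000
    min_exonic_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        self.subjects = tuple(self.subjects)
        self.captures = tuple(int(c) for c in self.captures)
        self.class_counts = {k: tuple(int(x) for x in v) for k, v in self.class_counts.items()}
        self.validate()

    def validate(self) -> None:
        n_subj = len(self.subjects)
        if len(self.captures) != n_subj:
            raise ValidationError("captures length must match subjects")
        for cls, counts in self.class_counts.items():
            if cls not in CELL_CLASSES:
                raise ValidationError(f"unknown cell class {cls!r}")
            if len(counts) != n_subj:
                raise ValidationError(f"class {cls!r}: counts length != subjects")
            if any(c < 0 for c in counts):
                raise ValidationError(f"class {cls!r}: negative count")
        for s, subject in enumerate(self.subjects):
            total = sum(self.class_counts.get(cls, (0,) * n_subj)[s] for cls in CELL_CLASSES)
            if total != self.captures[s]:
                raise ValidationError(
                    f"subject {subject!r}: class counts sum to {total}, "
                    f"capture is {self.captures[s]}"
                )
        if self.margin <= 0 or self.margin >= self.hormone_ratio_max:
            raise ValidationError("margin must lie in (0, hormone_ratio_max)")

    def class_total(self, cls: str) -> int:
        return sum(self.class_counts.get(cls, (0,) * len(self.subjects)))


@dataclass
class SyntheticTruth:
    """Planted ground truth: class per cell, role per transcript."""

    cell_class: dict[str, str]
    transcript_role: dict[str, str]  # marker | tf_program | de | null
    de_direction: dict[str, str]  # transcript -> beta_up | alpha_up
    de_fold: dict[str, float]

    def cells_of_class(self, cls: str) -> list[str]:
        return [c for c, k in self.cell_class.items() if k == cls]

    def de_transcripts(self, direction: str | None = None) -> list[str]:
        return [
            t
            for t, d in self.de_direction.items()
            if direction is None or d == direction
        ]

    def null_transcripts(self) -> list[str]:
        return [t for t, r in self.transcript_role.items() if r == "null"]


def default_study_config(seed: int = 0) -> FixtureConfig:
    """The study-emulation capture: 448 cells over three subjects.

    Per-subject splits follow the emulated study where it reports them
    (alpha 33/15/70, beta 32/33/40, delta 0/1/5, low-exonic 22/2/23); the
    remaining exclusion classes are allocated by a fixed documented rule
    (low-read 4/0/2, bihormonal 45/18/38, doublet 2/13/3, exocrine 0/2/45)
    so that each subject's classes sum to its capture count (138/84/226).
    """
    return FixtureConfig(
        subjects=("S1", "S2", "S3"),
        captures=(138, 84, 226),
        class_counts={
            "alpha": (33, 15, 70),
            "beta": (32, 33, 40),
            "delta": (0, 1, 5),
            "exocrine": (0, 2, 45),
            "doublet": (2, 13, 3),
            "bihormonal": (45, 18, 38),
            "low_read": (4, 0, 2),
            "low_exonic": (22, 2, 23),
        },
        seed=seed,
    )


def _build_transcripts(config: FixtureConfig):
    """Transcript table: (transcript_id, gene, role)."""
    table: list[tuple[str, str, str]] = []
    for gene, parts in HORMONE_TRANSCRIPTS.items():
        for tid, _ in parts:
            table.append((tid, gene, "marker"))
    table.append((REG1A_TRANSCRIPT[0], REG1A_TRANSCRIPT[1], "marker"))
    for gene, tid in TF_TRANSCRIPTS.items():
        table.append((tid, gene, "tf_program"))
    for i in range(config.n_de_per_direction):
        table.append((f"BUP{i + 1:03d}.1", f"BUP{i + 1:03d}", "de_beta_up"))
    for i in range(config.n_de_per_direction):
        table.append((f"AUP{i + 1:03d}.1", f"AUP{i + 1:03d}", "de_alpha_up"))
    for i in range(config.n_null):
        table.append((f"NUL{i + 1:04d}.1", f"NUL{i + 1:04d}", "null"))
    return table


def generate_fixture(
    config: FixtureConfig,
) -> tuple[ExpressionMatrix, list[CellRecord], SyntheticTruth]:
    """Generate one capture: matrix, metadata records, and ground truth.

    Deterministic given ``config.seed``.  Construction guarantees:

    * mono-hormonal endocrine cells keep their secondary/primary hormone
      ratio below ``hormone_ratio_max - margin``;
    * bi-hormonal cells draw that ratio uniformly from
      ``(hormone_ratio_max + margin, 1]``;
    * doublets co-express REG1A and one hormone above marker level;
    * low_read / low_exonic cells violate exactly their own metadata
      threshold, all other cells satisfy both;
    * planted DE transcripts differ between alpha and beta means by
      ``de_fold``; null transcripts share one mean everywhere.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    transcripts = _build_transcripts(config)
    transcript_ids = [t for t, _, _ in transcripts]
    gene_of = {t: g for t, g, _ in transcripts}
    t_index = {t: i for i, t in enumerate(transcript_ids)}

    role_of: dict[str, str] = {}
    de_direction: dict[str, str] = {}
    de_fold: dict[str, float] = {}
    for tid, _, role in transcripts:
        if role.startswith("de_"):
            role_of[tid] = "de"
            de_direction[tid] = role.removeprefix("de_")
            de_fold[tid] = config.de_fold
        else:
            role_of[tid] = role

    cells: list[CellRecord] = []
    cell_class: dict[str, str] = {}
    columns: list[np.ndarray] = []

    def noise(n: int = 1) -> np.ndarray:
        if config.sigma == 0:
            return np.ones(n)
        return np.exp(rng.normal(0.0, config.sigma, size=n))

    def set_gene(col: np.ndarray, gene: str, level: float) -> None:
        if gene in HORMONE_TRANSCRIPTS:
            for tid, frac in HORMONE_TRANSCRIPTS[gene]:
                col[t_index[tid]] = level * frac
        elif gene == "REG1A":
            col[t_index[REG1A_TRANSCRIPT[0]]] = level
        else:
            col[t_index[TF_TRANSCRIPTS[gene]]] = level

    def hormone_background(col: np.ndarray, skip: set[str]) -> None:
        # secondary hormones at scaled background, capped well under the
        # ratio threshold so mono-hormonal QC calls are noise-robust
        cap = 0.5 * (config.hormone_ratio_max - config.margin) * config.marker_level
        for gene in HORMONE_TRANSCRIPTS:
            if gene in skip:
                continue
            level = min(config.background_level * float(noise(1)[0]), cap)
            set_gene(col, gene, level)

    program = [(t_index[tid], role) for tid, _, role in transcripts
               if role not in ("marker", "tf_program")]
    prog_idx = np.array([i for i, _ in program], dtype=int)
    beta_up_mask = np.array([r == "de_beta_up" for _, r in program])
    alpha_up_mask = np.array([r == "de_alpha_up" for _, r in program])

    def program_block(col: np.ndarray, cls: str) -> None:
        # shared expression program with planted DE between alpha and beta
        if prog_idx.size == 0:
            return
        levels = np.full(prog_idx.size, config.de_base_level)
        if cls == "beta":
            levels[beta_up_mask] *= config.de_fold
        elif cls == "alpha":
            levels[alpha_up_mask] *= config.de_fold
        values = levels * noise(prog_idx.size)
        if config.dropout > 0:
            values[rng.random(prog_idx.size) < config.dropout] = 0.0
        col[prog_idx] = values

    def tf_block(col: np.ndarray, cls: str) -> None:
        for gene, level in TF_PROGRAMS.get(cls, {}).items():
            set_gene(col, gene, level * float(noise(1)[0]))

    def endocrine_column(cls: str) -> np.ndarray:
        col = np.zeros(len(transcripts))
        hormone = CLASS_HORMONE[cls]
        set_gene(col, hormone, config.marker_level * float(noise(1)[0]))
        hormone_background(col, skip={hormone})
        tf_block(col, cls)
        program_block(col, cls)
        return col

    def exocrine_column() -> np.ndarray:
        # hormones exactly zero: exocrine cells carry no endocrine hormone
        # signal and must pass the ratio filter via the no-hormone path
        col = np.zeros(len(transcripts))
        set_gene(col, "REG1A", config.marker_level * float(noise(1)[0]))
        tf_block(col, "exocrine")
        program_block(col, "exocrine")
        return col

    def doublet_column(k: int) -> np.ndarray:
        # REG1A + one hormone, emulating an exocrine/endocrine co-capture
        col = np.zeros(len(transcripts))
        hormone = ("GCG", "INS", "SST")[k % 3]
        set_gene(col, "REG1A", config.marker_level * float(noise(1)[0]))
        set_gene(col, hormone, config.marker_level * float(noise(1)[0]))
        tf_block(col, "exocrine")
        program_block(col, "doublet")
        return col

    def bihormonal_column(k: int) -> np.ndarray:
        col = np.zeros(len(transcripts))
        primary, secondary = [
            ("INS", "GCG"),
            ("GCG", "INS"),
            ("INS", "SST"),
            ("GCG", "SST"),
        ][k % 4]
        primary_level = config.marker_level * float(noise(1)[0])
        ratio = rng.uniform(config.hormone_ratio_max + config.margin, 1.0)
        set_gene(col, primary, primary_level)
        set_gene(col, secondary, ratio * primary_level)
        program_block(col, "bihormonal")
        return col

    builders = {
        "alpha": lambda k: endocrine_column("alpha"),
        "beta": lambda k: endocrine_column("beta"),
        "delta": lambda k: endocrine_column("delta"),
        "exocrine": lambda k: exocrine_column(),
        "doublet": doublet_column,
        "bihormonal": bihormonal_column,
        # metadata-excluded cells get a generic endocrine-like profile;
        # the pipeline never reads their expression
        "low_read": lambda k: endocrine_column("alpha"),
        "low_exonic": lambda k: endocrine_column("beta"),
    }

    for s, subject in enumerate(config.subjects):
        idx = 0
        for cls in CELL_CLASSES:
            count = config.class_counts.get(cls, (0,) * len(config.subjects))[s]
            for k in range(count):
                idx += 1
                cell_id = f"{subject}_C{idx:03d}"
                if cls == "low_read":
                    reads = int(rng.integers(200_000, config.min_reads))
                else:
                    reads = int(rng.integers(1_020_000, 8_210_000))
                if cls == "low_exonic":
                    exonic = float(rng.uniform(0.05, config.min_exonic_fraction - 0.001))
                else:
                    exonic = float(rng.uniform(0.344, 0.926))
                cells.append(CellRecord(cell_id, subject, reads, exonic))
                cell_class[cell_id] = cls
                columns.append(builders[cls](k))

    values = np.column_stack(columns) if columns else np.empty((len(transcripts), 0))
    matrix = ExpressionMatrix(transcript_ids, gene_of, [c.cell_id for c in cells], values)
    truth = SyntheticTruth(cell_class, role_of, de_direction, de_fold)
    return matrix, cells, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> Path:
    """Serialize ground truth as two-section TSV (cells, then transcripts)."""
    path = Path(path)
    lines = ["kind\tid\tlabel\tdetail"]
    for cell, cls in truth.cell_class.items():
        lines.append(f"cell\t{cell}\t{cls}\t")
    for tid, role in truth.transcript_role.items():
        detail = ""
        if role == "de":
            detail = f"{truth.de_direction[tid]}:{truth.de_fold[tid]:g}"
        lines.append(f"transcript\t{tid}\t{role}\t{detail}")
    path.write_text("\n".join(lines) + "\n")
    return path


def simulate_to_dir(
    config: FixtureConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Emit matrix TSV + metadata TSV + truth TSV for a config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, cells, truth = generate_fixture(config)
    paths = {
        "matrix": write_matrix(matrix, out / "matrix.tsv", "tsv"),
        "metadata": write_cell_metadata(cells, out / "cells.tsv"),
        "truth": write_truth(truth, out / "truth.tsv"),
    }
    return paths
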