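"""Cell-level quality control.

Three filters, applied in a fixed order:

1. read depth — drop cells with fewer than ``min_reads`` total reads
   (strict ``<``);
2. exonic alignment — drop cells whose fraction of reads aligned to exons
   is below ``min_exonic_fraction`` (strict ``<``; low values indicate
   genomic-DNA contamination);
3. hormone ratio — profile each cell's summed RPKM over the islet hormone
   panel (INS, GCG, SST by default) and drop cells whose second-highest
   hormone exceeds ``hormone_ratio_max`` times the highest (strict ``>``).
   Cells expressing none of the panel hormones (e.g. exocrine cells) pass
   this filter and are resolved at typing.

The ratio filter operates on raw RPKM: it is part of QC and runs before the
between-cell normalization applied ahead of statistical analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_core import (
    CellRecord,
    ExpressionMatrix,
    StageReport,
    ValidationError,
    make_stage_report,
)

__all__ = [
    "HormoneCall",
    "filter_low_reads",
    "filter_low_exonic",
    "hormone_profile",
    "filter_bihormonal",
]


@dataclass
class HormoneCall:
    """Primary/secondary hormone identities of one cell.

    ``secondary_ratio`` is secondary RPKM / primary RPKM (gene-level sums);
    it is ``None`` when the cell expresses no panel hormone.  Ties are
    broken by fixed panel order, which can only matter for the arbitrary
    primary/secondary naming, never for the verdict.
    """

    cell_id: str
    primary_hormone: str | None
    primary_rpkm: float
    secondary_hormone: str | None
    secondary_rpkm: float
    secondary_ratio: float | None
    verdict: str  # mono_hormonal | bihormonal_excluded | no_hormone


def filter_low_reads(
    cells: Sequence[CellRecord], min_reads: int
) -> tuple[list[CellRecord], list[CellRecord], StageReport]:
    """Partition cells by total read count (strict ``< min_reads`` excludes)."""
    retained, excluded = [], []
    for cell in cells:
        if cell.total_reads < 0:
            raise ValidationError(f"cell {cell.cell_id!r}: negative read count")
        if cell.total_reads < min_reads:
            cell.exclude("excluded_low_reads", "low_reads")
            excluded.append(cell)
        else:
            retained.append(cell)
    report = make_stage_report(
        "low_reads", retained, excluded, {"min_reads": min_reads}
    )
    return retained, excluded, report


def filter_low_exonic(
    cells: Sequence[CellRecord], min_exonic_fraction: float
) -> tuple[list[CellRecord], list[CellRecord], StageReport]:
    """Partition cells by exonic alignment fraction (strict ``<`` excludes)."""
    retained, excluded = [], []
    for cell in cells:
        if not 0.0 <= cell.exonic_fraction <= 1.0:
            raise ValidationError(
                f"cell {cell.cell_id!r}: exonic_fraction {cell.exonic_fraction} "
                "outside [0, 1]"
            )
        if cell.exonic_fraction < min_exonic_fraction:
            cell.exclude("excluded_low_exonic", "low_exonic")
            excluded.append(cell)
        else:
            retained.append(cell)
    report = make_stage_report(
        "low_exonic", retained, excluded, {"min_exonic_fraction": min_exonic_fraction}
    )
    return retained, excluded, report


def hormone_profile(
    matrix: ExpressionMatrix,
    cell_id: str,
    hormone_panel: Sequence[str] = ("INS", "GCG", "SST"),
    hormone_ratio_max: float = 0.10,
) -> HormoneCall:
    """Call the primary/secondary hormone of one cell from gene-level RPKM.

    The primary hormone is the panel gene with the largest summed RPKM, the
    secondary the second largest; the verdict is ``bihormonal_excluded``
    iff secondary/primary exceeds ``hormone_ratio_max`` (strict ``>``), and
    ``no_hormone`` iff every panel hormone is exactly zero.
    """
    j = matrix.cell_index(cell_id)
    levels = np.array([matrix.gene_rpkm(g)[j] for g in hormone_panel])
    if np.all(levels == 0):
        return HormoneCall(cell_id, None, 0.0, None, 0.0, None, "no_hormone")
    # stable argsort on negated levels ties-breaks by panel order
    order = np.argsort(-levels, kind="stable")
    primary = int(order[0])
    secondary = int(order[1]) if len(levels) > 1 else None
    primary_rpkm = float(levels[primary])
    secondary_rpkm = float(levels[secondary]) if secondary is not None else 0.0
    ratio = secondary_rpkm / primary_rpkm
    verdict = "bihormonal_excluded" if ratio > hormone_ratio_max else "mono_hormonal"
    return HormoneCall(
        cell_id,
        hormone_panel[primary],
        primary_rpkm,
        hormone_panel[secondary] if secondary is not None else None,
        secondary_rpkm,
        ratio,
        verdict,
    )


def filter_bihormonal(
    matrix: ExpressionMatrix,
    cells: Sequence[CellRecord],
    hormone_ratio_max: float = 0.10,
    hormone_panel: Sequence[str] = ("INS", "GCG", "SST"),
) -> tuple[list[CellRecord], list[CellRecord], StageReport, list[HormoneCall]]:
    """Exclude cells whose secondary/primary hormone ratio is > threshold.

    A ratio of exactly ``hormone_ratio_max`` is retained; cells with no
    panel hormone expression pass unconditionally.
    """
    retained, excluded, calls = [], [], []
    for cell in cells:
        call = hormone_profile(matrix, cell.cell_id, hormone_panel, hormone_ratio_max)
        calls.append(call)
        if call.verdict == "bihormonal_excluded":
            cell.exclude("excluded_bihormonal", "bihormonal")
            excluded.append(cell)
        else:
            retained.append(cell)
    report = make_stage_report(
        "bihormonal",
        retained,
        excluded,
        {"hormone_ratio_max": hormone_ratio_max, "hormone_panel": list(hormone_panel)},
    )
    return retained, excluded, report, calls
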