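"""Two-stage differential expression between beta- and alpha-cells.

Design: subjects are split into a discovery set and a validation set.  In
discovery, transcripts passing a prevalence filter (RPKM > ``de_min_rpkm``
in at least ``de_min_cell_fraction`` of the stage's cells) are tested with
one-way two-group ANOVA on linear-scale values; p-values are
Bonferroni-corrected over the discovery test count, and candidates are
transcripts with adjusted p < alpha and |signed fold change| > the fold
threshold.  Candidates are then re-tested on the validation subjects only,
with Bonferroni correction over the number of candidates carried forward
(separately per direction by default).  A transcript *replicates* when both
stages are significant with the same sign.

Fold change is the ratio of group means with the negative-reciprocal
display convention: ``+mean_beta/mean_alpha`` when beta is higher, else
``-mean_alpha/mean_beta``, so |fc| >= 1 always and the sign carries the
direction (positive = beta_up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .io_core import (
    CellRecord,
    ExpressionMatrix,
    PipelineConfig,
    StageReport,
    ValidationError,
)
from .celltype import CellTypeCall

__all__ = [
    "StageStats",
    "DETestResult",
    "select_testable_transcripts",
    "anova_two_group",
    "signed_fold_change",
    "bonferroni_adjust",
    "two_stage_de",
]


@dataclass
class StageStats:
    """Per-stage statistics of one transcript (group A = beta, B = alpha)."""

    n_a: int
    n_b: int
    raw_p: float
    adjusted_p: float
    signed_fc: float  # may be +/-inf when one group mean is zero
    fc_capped: bool = False  # True when signed_fc is an infinity sentinel


@dataclass
class DETestResult:
    transcript_id: str
    gene: str
    direction: str | None  # beta_up | alpha_up (by discovery fold-change sign)
    discovery: StageStats | None = None
    validation: StageStats | None = None
    verdict: str = "not_tested"  # replicated | discovery_only | not_significant | not_tested


def select_testable_transcripts(
    matrix: ExpressionMatrix,
    cell_ids: Sequence[str],
    de_min_rpkm: float = 50.0,
    de_min_cell_fraction: float = 0.25,
) -> list[str]:
    """Transcripts with RPKM strictly > ``de_min_rpkm`` in at least
    ``de_min_cell_fraction`` of the given cells (``ceil`` of the fraction)."""
    if not cell_ids:
        raise ValidationError("cannot select testable transcripts from no cells")
    idx = [matrix.cell_index(c) for c in cell_ids]
    sub = matrix.values[:, idx]
    need = math.ceil(de_min_cell_fraction * len(cell_ids))
    counts = (sub > de_min_rpkm).sum(axis=1)
    return [t for t, c in zip(matrix.transcript_ids, counts) if c >= need]


def anova_two_group(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA for two groups.

    Returns ``(F, p)`` with 1 and ``n_a + n_b - 2`` degrees of freedom;
    F equals the square of the pooled-variance two-sample t statistic.
    Degenerate inputs: when both groups are constant, F is 0 (p = 1) for
    equal means and infinite (p = 0) for different means.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("non-finite value in ANOVA input")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf, 0.0
    res = scipy.stats.f_oneway(a, b)
    return float(res.statistic), float(res.pvalue)


def signed_fold_change(mean_a: float, mean_b: float) -> tuple[float | None, bool]:
    """Signed ratio of two non-negative group means.

    ``+mean_a/mean_b`` when ``mean_a >= mean_b`` else ``-mean_b/mean_a``;
    a zero denominator yields a signed infinity with the capped flag set;
    both means zero yields ``(None, False)`` (fold change undefined).
    """
    if mean_a < 0 or mean_b < 0:
        raise ValidationError("group means must be non-negative")
    if mean_a == 0.0 and mean_b == 0.0:
        return None, False
    if mean_a >= mean_b:
        if mean_b == 0.0:
            return math.inf, True
        return mean_a / mean_b, False
    if mean_a == 0.0:
        return -math.inf, True
    return -mean_b / mean_a, False


def bonferroni_adjust(raw_p: float, n_tests: int) -> float:
    """Bonferroni family-wise correction: ``min(1, raw_p * n_tests)``."""
    if not 0.0 <= raw_p <= 1.0:
        raise ValidationError(f"raw p-value {raw_p} outside [0, 1]")
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    return min(1.0, raw_p * n_tests)


def _stage_stats(
    matrix: ExpressionMatrix,
    transcript: str,
    beta_cells: Sequence[str],
    alpha_cells: Sequence[str],
    log2: bool,
) -> tuple[StageStats | None, float]:
    """Raw per-transcript stats for one stage (adjusted_p filled later).

    Returns ``(stats, raw_p)``; ``stats`` is ``None`` when the fold change
    is undefined (both group means zero).
    """
    row = matrix.values[matrix.transcript_ids.index(transcript)]
    ai = [matrix.cell_index(c) for c in beta_cells]
    bi = [matrix.cell_index(c) for c in alpha_cells]
    va, vb = row[ai], row[bi]
    fc, capped = signed_fold_change(float(va.mean()), float(vb.mean()))
    if fc is None:
        return None, 1.0
    if log2:
        f, p = anova_two_group(np.log2(va + 1.0), np.log2(vb + 1.0))
    else:
        f, p = anova_two_group(va, vb)
    stats = StageStats(
        n_a=len(va), n_b=len(vb), raw_p=p, adjusted_p=p, signed_fc=fc, fc_capped=capped
    )
    return stats, p


def _passes(stats: StageStats, alpha: float, fc_threshold: float) -> bool:
    return stats.adjusted_p < alpha and abs(stats.signed_fc) > fc_threshold


def two_stage_de(
    matrix: ExpressionMatrix,
    type_calls: Sequence[CellTypeCall],
    subject_of: Mapping[str, str] | Sequence[CellRecord],
    discovery_subjects: Sequence[str],
    validation_subjects: Sequence[str],
    config: PipelineConfig | None = None,
    include_all_tested: bool = False,
    prevalence_matrix: ExpressionMatrix | None = None,
) -> tuple[list[DETestResult], StageReport]:
    """Run the discovery/validation DE analysis between beta- and alpha-cells.

    ``matrix`` carries the analysis values (normally quantile-normalized);
    ``prevalence_matrix`` (default: same matrix) the values the prevalence
    filter thresholds.  By default the result list contains the candidates
    carried into validation, each with verdict ``replicated`` or
    ``discovery_only``; ``include_all_tested`` adds the discovery-tested
    non-candidates (``not_significant`` / ``not_tested``).
    """
    cfg = config or PipelineConfig()
    if not isinstance(subject_of, Mapping):
        subject_of = {r.cell_id: r.subject_id for r in subject_of}
    prevalence_matrix = prevalence_matrix or matrix

    def stage_groups(subjects: Sequence[str]) -> tuple[list[str], list[str]]:
        subjects = set(subjects)
        beta = [
            c.cell_id
            for c in type_calls
            if c.type == "beta" and subject_of[c.cell_id] in subjects
        ]
        alpha = [
            c.cell_id
            for c in type_calls
            if c.type == "alpha" and subject_of[c.cell_id] in subjects
        ]
        return beta, alpha

    disc_beta, disc_alpha = stage_groups(discovery_subjects)
    val_beta, val_alpha = stage_groups(validation_subjects)
    for name, group in (
        ("discovery beta", disc_beta),
        ("discovery alpha", disc_alpha),
        ("validation beta", val_beta),
        ("validation alpha", val_alpha),
    ):
        if len(group) < 2:
            raise ValidationError(f"{name} group has fewer than 2 cells")

    testable = select_testable_transcripts(
        prevalence_matrix,
        disc_beta + disc_alpha,
        cfg.de_min_rpkm,
        cfg.de_min_cell_fraction,
    )
    n_tests = len(testable)

    results: list[DETestResult] = []
    candidates: list[DETestResult] = []
    for transcript in testable:
        stats, raw_p = _stage_stats(matrix, transcript, disc_beta, disc_alpha, cfg.log2_de)
        gene = matrix.gene_of[transcript]
        if stats is None:
            results.append(DETestResult(transcript, gene, None, verdict="not_tested"))
            continue
        stats.adjusted_p = bonferroni_adjust(raw_p, n_tests)
        direction = "beta_up" if stats.signed_fc > 0 else "alpha_up"
        result = DETestResult(transcript, gene, direction, discovery=stats)
        if _passes(stats, cfg.alpha, cfg.fc_threshold):
            candidates.append(result)
        else:
            result.verdict = "not_significant"
        results.append(result)

    # validation multiplicity: per direction by default (pooled if configured)
    n_by_direction = {
        "beta_up": sum(1 for r in candidates if r.direction == "beta_up"),
        "alpha_up": sum(1 for r in candidates if r.direction == "alpha_up"),
    }
    for result in candidates:
        stats, raw_p = _stage_stats(
            matrix, result.transcript_id, val_beta, val_alpha, cfg.log2_de
        )
        n_corr = len(candidates) if cfg.pooled_validation_correction else n_by_direction[result.direction]
        if stats is None:
            result.verdict = "discovery_only"
            continue
        stats.adjusted_p = bonferroni_adjust(raw_p, max(n_corr, 1))
        result.validation = stats
        same_sign = (stats.signed_fc > 0) == (result.discovery.signed_fc > 0)
        if _passes(stats, cfg.alpha, cfg.fc_threshold) and same_sign:
            result.verdict = "replicated"
        else:
            result.verdict = "discovery_only"

    output = results if include_all_tested else candidates
    report = StageReport(
        stage="two_stage_de",
        n_input=n_tests,
        n_excluded=n_tests - len(candidates),
        n_retained=len(candidates),
        parameters={
            "discovery_cells": {"beta": len(disc_beta), "alpha": len(disc_alpha)},
            "validation_cells": {"beta": len(val_beta), "alpha": len(val_alpha)},
            "n_tests_discovery": n_tests,
            "n_candidates": dict(n_by_direction),
            "n_replicated": sum(1 for r in candidates if r.verdict == "replicated"),
            "alpha": cfg.alpha,
            "fc_threshold": cfg.fc_threshold,
            "de_min_rpkm": cfg.de_min_rpkm,
            "de_min_cell_fraction": cfg.de_min_cell_fraction,
        },
    )
    report.validate()
    return output, report
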