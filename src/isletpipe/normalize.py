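"""Between-cell quantile normalization.

Forces every cell's expression distribution onto a common reference: the
across-cell mean of order statistics.  After normalization each cell's
sorted value vector is identical; within-cell ranks are preserved.  Tied
values within a cell (including the zero block of sparse cells) receive the
mean of the reference values their positions span, the common convention.
"""

from __future__ import annotations

import numpy as np

from .io_core import ExpressionMatrix, ValidationError

__all__ = ["quantile_normalize", "quantile_normalize_values"]


def quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize a transcripts x cells array across cells (columns)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("expected a 2-D transcripts x cells array")
    n_transcripts, n_cells = values.shape
    if n_cells < 2:
        raise ValidationError("quantile normalization needs at least 2 cells")
    if not np.all(np.isfinite(values)):
        raise ValidationError("NaN or infinite value in input")
    if n_transcripts == 0:
        return values.copy()

    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cells):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # tie groups: runs of equal values get the mean reference over the run
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_transcripts]))
        ref_cumsum = np.concatenate(([0.0], np.cumsum(reference)))
        group_means = (ref_cumsum[ends] - ref_cumsum[starts]) / (ends - starts)
        assigned = np.repeat(group_means, ends - starts)
        out[order, j] = assigned
    return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize an expression matrix across its cells."""
    return matrix.with_values(quantile_normalize_values(matrix.values))
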