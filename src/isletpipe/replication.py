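"""In-silico replication of external alpha/beta marker-gene signatures.

Given a signature — a list of genes (optionally pinned to a transcript)
each claimed to be enriched in alpha- or beta-cells by an external study —
test every signature transcript against this dataset's pooled alpha and
beta cells (one stage, no discovery/validation split), Bonferroni-correct
over the number of signature transcripts actually tested (per signature and
direction, never the full transcriptome), and classify each entry:

* ``concordant``   — significant with the claimed direction;
* ``discordant``   — significant with the opposite direction (the
  interesting cross-species/cross-ancestry disagreements);
* ``not_significant`` — tested but not passing the adjusted-p / fold cuts;
* ``not_tested``   — absent from the matrix or failing the prevalence
  filter.

Signatures for the emulated study's comparisons (mouse islet marker genes,
and the human alpha/beta transcript lists) ship as packaged data assets,
loadable by name via :func:`packaged_signature`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from .io_core import (
    ExpressionMatrix,
    PipelineConfig,
    SchemaError,
    ValidationError,
)
from .celltype import CellTypeCall
from .de import anova_two_group, bonferroni_adjust, select_testable_transcripts, signed_fold_change

__all__ = [
    "SignatureEntry",
    "SignatureSet",
    "ReplicationResult",
    "load_signature",
    "packaged_signature",
    "PACKAGED_SIGNATURES",
    "replicate_signature",
]

_DIRECTIONS = ("alpha_up", "beta_up")

#: names of the signature tables shipped with the package
PACKAGED_SIGNATURES = ("human_alpha", "human_beta", "mouse")


@dataclass(frozen=True)
class SignatureEntry:
    gene: str
    transcript_id: str | None
    claimed_direction: str  # alpha_up | beta_up
    species: str = "human"


@dataclass
class SignatureSet:
    name: str
    entries: list[SignatureEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.gene, e.transcript_id)
            if key in seen:
                raise ValidationError(f"duplicate signature entry {key}")
            seen.add(key)
            if e.claimed_direction not in _DIRECTIONS:
                raise SchemaError(
                    f"unknown direction {e.claimed_direction!r} for gene {e.gene!r}"
                )


@dataclass
class ReplicationResult:
    entry: SignatureEntry
    transcript_tested: str | None  # best-supported transcript
    raw_p: float | None
    adjusted_p: float | None
    signed_fc: float | None  # positive = beta_up
    class_: str  # concordant | discordant | not_significant | not_tested


def load_signature(path: str | Path, name: str | None = None) -> SignatureSet:
    """Read a signature TSV with columns gene, transcript, direction, species."""
    path = Path(path)
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = {"gene", "direction"} - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"{path}: missing signature columns {sorted(missing)}")
        for row in reader:
            entries.append(
                SignatureEntry(
                    gene=row["gene"],
                    transcript_id=(row.get("transcript") or None),
                    claimed_direction=row["direction"],
                    species=row.get("species") or "human",
                )
            )
    return SignatureSet(name or path.stem, entries)


def packaged_signature(name: str) -> SignatureSet:
    """Load one of the signatures shipped with the package."""
    if name not in PACKAGED_SIGNATURES:
        raise ValidationError(
            f"unknown packaged signature {name!r}; available: {PACKAGED_SIGNATURES}"
        )
    ref = resources.files("isletpipe").joinpath(f"data/signature_{name}.tsv")
    with resources.as_file(ref) as path:
        return load_signature(path, name=name)


def replicate_signature(
    matrix: ExpressionMatrix,
    type_calls: Sequence[CellTypeCall],
    signature: SignatureSet,
    config: PipelineConfig | None = None,
) -> tuple[list[ReplicationResult], dict[str, int]]:
    """Test a signature against pooled alpha vs beta cells.

    The prevalence filter (RPKM > ``de_min_rpkm`` in >= ``de_min_cell_fraction``
    of cells) runs over the pooled alpha+beta cells; the Bonferroni
    denominator is the number of signature transcripts passing it, counted
    separately per claimed direction.  Fold-change sign convention is
    beta-over-alpha (positive = higher in beta).
    """
    cfg = config or PipelineConfig()
    beta = [c.cell_id for c in type_calls if c.type == "beta"]
    alpha = [c.cell_id for c in type_calls if c.type == "alpha"]
    if len(beta) < 2 or len(alpha) < 2:
        raise ValidationError("both alpha and beta cells are required for replication")
    pooled = beta + alpha
    testable = set(
        select_testable_transcripts(matrix, pooled, cfg.de_min_rpkm, cfg.de_min_cell_fraction)
    )
    bi = [matrix.cell_index(c) for c in beta]
    ai = [matrix.cell_index(c) for c in alpha]
    t_row = {t: i for i, t in enumerate(matrix.transcript_ids)}
    by_gene: dict[str, list[str]] = {}
    for t in matrix.transcript_ids:
        by_gene.setdefault(matrix.gene_of[t], []).append(t)

    # resolve each entry to the transcripts it is tested on
    tested_transcripts: dict[SignatureEntry, list[str]] = {}
    for entry in signature.entries:
        if entry.transcript_id is not None:
            hits = [entry.transcript_id] if entry.transcript_id in testable else []
        else:
            hits = [t for t in by_gene.get(entry.gene, []) if t in testable]
        tested_transcripts[entry] = hits

    # Bonferroni denominator: tested signature transcripts per direction
    n_tested = {
        d: sum(
            len(hits)
            for entry, hits in tested_transcripts.items()
            if entry.claimed_direction == d
        )
        for d in _DIRECTIONS
    }

    results: list[ReplicationResult] = []
    for entry in signature.entries:
        hits = tested_transcripts[entry]
        if not hits:
            results.append(ReplicationResult(entry, None, None, None, None, "not_tested"))
            continue
        best: tuple[float, float, float, str] | None = None  # adj_p, raw_p, fc, tid
        for tid in hits:
            row = matrix.values[t_row[tid]]
            vb, va = row[bi], row[ai]
            fc, _ = signed_fold_change(float(vb.mean()), float(va.mean()))
            if fc is None:
                continue
            _, raw_p = anova_two_group(vb, va)
            adj = bonferroni_adjust(raw_p, max(n_tested[entry.claimed_direction], 1))
            if best is None or adj < best[0]:
                best = (adj, raw_p, fc, tid)
        if best is None:
            results.append(ReplicationResult(entry, None, None, None, None, "not_tested"))
            continue
        adj, raw_p, fc, tid = best
        significant = adj < cfg.alpha and abs(fc) > cfg.fc_threshold
        observed = "beta_up" if fc > 0 else "alpha_up"
        if not significant:
            klass = "not_significant"
        elif observed == entry.claimed_direction:
            klass = "concordant"
        else:
            klass = "discordant"
        results.append(ReplicationResult(entry, tid, raw_p, adj, fc, klass))

    summary = {k: 0 for k in ("concordant", "discordant", "not_significant", "not_tested")}
    for r in results:
        summary[r.class_] += 1
    return results, summary
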