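# Methods

## Data model

The unit of analysis is the transcript, not the gene: an expression matrix
holds non-negative RPKM values for transcripts × cells, with a
transcript → gene map. Several transcripts may share a gene (the two INS
transcripts in the default fixture); gene-level expression, wherever a rule
needs it (hormone profiling, doublet markers, type calls), is the sum of
that gene's transcript RPKMs. Summation is a deliberate choice — the
alternative (max over transcripts) differs only for multi-transcript genes
and makes gene-level calls depend on annotation granularity.

Per-cell metadata carries the donor subject, total sequenced reads and the
fraction of reads aligned to exons. Cell status is monotone: once a cell is
excluded at some stage it is never re-included, and every stage emits a
ledger entry with `input = excluded + retained` (checked, per subject and in
total). The pipeline asserts global conservation — captured cells equal
typed cells plus the sum of stage exclusions — on every run.

## QC filters

Three filters, in a fixed order that the ledger semantics depend on
(filters are not order-independent, since later filters see fewer cells):

| filter | rule | default |
|---|---|---|
| read depth | exclude iff `total_reads < min_reads` | 1,000,000 reads |
| exonic alignment | exclude iff `exonic_fraction < min_exonic_fraction` | 0.30 |
| hormone ratio | exclude iff secondary/primary hormone RPKM `> hormone_ratio_max` | 0.10 |

All three use strict inequalities; a cell at exactly 1,000,000 reads, 30%
exonic, or ratio 0.10 is retained. The hormone profile of a cell is taken
over a panel (INS, GCG, SST by default): primary = largest gene-level RPKM,
secondary = second largest, ties broken by panel order (the tie-break can
only relabel primary/secondary, never change a verdict). Cells expressing
no panel hormone at all pass the ratio filter — exocrine cells must survive
QC to be typed later. The ratio is computed on raw RPKM because the filter
is part of QC, upstream of the normalization applied before statistics.

## Quantile normalization

Between-cell quantile normalization maps every cell onto the across-cell
mean of order statistics. Ties within a cell (including the zero block of
sparse cells) receive the mean of the reference values their positions
span; this matches `limma::normalizeQuantiles(ties=TRUE)`, against which the
implementation is cross-checked in the tests (frozen values) alongside an
independent loop-based oracle. Consequences users should know: all zeros of
a cell collapse to one shared low value, and the transformation is
idempotent and rank-preserving within cells.

Whether the downstream RPKM thresholds (500 for "highly expressed", 50 for
the DE prevalence filter, marker and doublet cuts) refer to raw or
normalized values is genuinely ambiguous in this kind of protocol
description; both are supported via `thresholds_on: normalized|raw`
(default `normalized`, since typing and DE happen after normalization).
On the default fixture both settings recover identical type counts.

## Cell typing

Highly expressed transcripts are those with RPKM ≥ 500 in ≥ 2% of cells
(inclusive thresholds; the cell cut is `ceil(fraction × n_cells)`). Cells
are clustered agglomeratively on the per-transcript standardized
(mean 0, sd 1) values of the highly expressed lineage-panel transcripts.
The default lineage panel is {INS, GCG, SST, PPY, GHRL, REG1A, PDX1, ARX,
MAFA, MAFB, NKX6-1, NEUROG3, PTF1A, CPA1}, overridable by config — it is an
editorial choice of canonical islet lineage genes, not a published list.

Ward linkage on Euclidean distance is the default. Single, complete and
average linkage are available, but on realistic noisy data they chain:
low-k cuts peel off outlier singleton cells instead of separating the main
cell types, whereas Ward recovers the four planted types exactly at k = 4
on the default fixture. The dendrogram provides context and reporting
(Newick export); the final labels do not depend on it.

Doublets are cells with ≥ 2 of the four lineage markers REG1A/GCG/INS/SST
above 500 RPKM (gene-level, strict `>`). Stage ordering makes doublet and
bi-hormonal exclusions complementary by construction: ratio-filtered cells
never reach doublet detection. After doublet removal, each cell's type is
the one named by its maximal lineage marker (GCG → α, INS → β, δ → SST,
REG1A → exocrine) when that marker is ≥ 500 RPKM, else `unassigned`.
Marker-maximal typing is deterministic and permutation-invariant, which is
why it — rather than a dendrogram cut — produces the final labels.

## Two-stage differential expression

Subjects are split into discovery (default S1, S2) and validation (default
S3) sets. Within a stage, the comparison is β-cells vs α-cells:

* **Prevalence filter**: transcripts with RPKM > 50 (strict) in at least
  25% of the stage's pooled α+β cells (`ceil`); stringent variants 0.42 and
  0.47 are config settings.
* **Test**: one-way two-group ANOVA on linear-scale normalized values,
  F with 1 and n₁+n₂−2 degrees of freedom (identical to the squared
  pooled-variance t). Linear scale is deliberate: the fold changes this
  design reports are linear-scale ratios of means, and a `log2_de` option
  exists for robustness checks. Degenerate inputs (both groups constant)
  yield F = 0, p = 1 at equal means.
* **Fold change**: signed ratio of group means; `+mean_β/mean_α` when β is
  higher, else `−mean_α/mean_β`, so |fc| ≥ 1 and the sign encodes
  direction. A zero denominator is reported as a signed-infinity sentinel
  with a capped flag; both means zero makes the transcript `not_tested`.
* **Multiplicity**: discovery p-values are Bonferroni-corrected over the
  discovery test count. Candidates (adjusted p < 0.05 and |fc| > 1.5) are
  carried into validation and corrected over the number of candidates per
  direction (a pooled single correction is config-switchable). All
  discovery candidates are carried forward, including those that fail
  validation — their verdict is `discovery_only`.

## Signature replication

External marker lists are tested one-stage against all pooled α and β
cells. The Bonferroni denominator is the number of signature transcripts
passing the prevalence filter, per signature and direction — never the full
transcriptome. Gene-level entries (no transcript pinned) are tested on all
of the gene's transcripts passing the filter and classified by the
best-supported transcript (minimum adjusted p). Three signature tables ship
with the package (`data/`): mouse α/β marker genes (gene-level) and human
α (23 transcripts) and β (50 transcripts) signature lists.

## Synthetic-data generator

The generator emulates the RPKM-level structure the analysis assumes, not
the sequencing process (no reads, UMIs, library-size effects or batch
structure). Per cell class:

* **Endocrine (α/β/δ)**: defining hormone at marker level (default 5,000
  RPKM) × lognormal noise (σ = 0.4); other hormones at background (default
  1 RPKM) × noise, capped so the secondary/primary ratio stays below
  `hormone_ratio_max − margin`; a modest type-specific transcription-factor
  program (e.g. ARX/MAFB in α, PDX1/MAFA/NKX6-1 in β). β-cells split INS
  over two transcripts (90/10) sharing the gene symbol.
* **Exocrine**: REG1A at marker level; the three hormones exactly zero, so
  these cells pass the ratio filter via the no-hormone path. (At a nonzero
  hormone background the secondary/primary ratio of a hormone-free cell
  would be ≈ 1 and QC would wrongly exclude it; real exocrine cells pass QC
  because their hormone signal is at detection floor, which exact zero
  models.)
* **Doublet**: REG1A plus one hormone, both at marker level — an
  exocrine/endocrine co-capture. These pass the hormone-ratio filter (only
  one hormone is high) and are caught by dual-marker doublet detection.
  Hormone+hormone doublets are not planted: they are indistinguishable
  from bi-hormonal artifacts and would already fall to the ratio filter.
* **Bi-hormonal artifact**: primary hormone at marker level; a second
  hormone at a ratio drawn uniformly from `(hormone_ratio_max + margin, 1]`.
* **low_read / low_exonic**: ordinary expression profiles whose metadata
  violate exactly their own threshold; every other cell satisfies both.
* **Expression program**: all cells share a base program (default 100 null
  transcripts at 200 RPKM × noise, 10% dropout). Planted DE transcripts
  (default 10 per direction) multiply the base mean by `de_fold` (default
  8) in the favored cell type only; dropout applies to program transcripts,
  never to the structural markers that define a cell's class.

The margin (default 0.02) keeps every planted cell's hormone ratio outside
`[0.08, 0.12]`, so QC decisions on fixtures are deterministic under noise
and the planted class counts are recovered exactly for any seed. The
default configuration is a 3-subject capture of 138/84/226 cells with
per-subject class counts (α 33/15/70, β 32/33/40, δ 0/1/5, exocrine 0/2/45,
doublet 2/13/3, bi-hormonal 45/18/38, low-read 4/0/2, low-exonic 22/2/23),
summing to 448 and yielding discovery groups of 65 β / 48 α and validation
groups of 40 β / 70 α.

What passing fixture tests shows: the filters implement their thresholds
exactly, the stage ledger is conserved, typing recovers planted classes,
and the two-stage design detects planted linear fold changes ≥ 4 at these
group sizes while Bonferroni keeps null transcripts out. What it does not
show: robustness to realistic biological covariance, subject batch effects,
ambient contamination, continuous cell states, or hormone ratios near the
threshold — real data near the 10% boundary will be noise-sensitive in a
way the margin construction deliberately avoids.

## Numerical choices and edge cases

* All threshold comparisons use exact floating-point semantics as stated
  (strict vs inclusive per rule); no epsilon is added.
* Quantile normalization requires ≥ 2 cells and rejects NaN input.
* Constant transcripts are dropped before standardization for clustering;
  a matrix of identical cells yields a dendrogram with all merge heights 0.
* ANOVA with fewer than 2 cells per group is an error; stages validate
  their group sizes before testing.
* Cuts of cell fractions always use `ceil(fraction × n_cells)`.
* The analysis stages consume no randomness; only the generator does, from
  a single seeded NumPy generator, so fixture runs are bit-reproducible.

## Problem sizes

The shipped configuration (448 cells, ~130 transcripts; 500-transcript null
variants in the type-I-error tests) runs the full pipeline in about a
second. The design scales to transcriptome-wide matrices — the costly steps
are quantile normalization (sort per cell) and per-transcript ANOVA, both
linear in transcripts — but the packaged studies are deliberately
desk-scale so the entire suite re-runs from scratch in seconds.
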