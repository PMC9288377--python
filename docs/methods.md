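# Methods

## Design and scope

The pipeline starts from per-cell-type gene × sample read-count matrices
(raw integers) and a design table assigning each sample a cell type
(EC, PC, AC, MG by default), a hemisphere (contralateral = control,
ipsilateral = ischemic) and a replicate index. The assumed design is the
sorted-NVU stroke layout: 4 cell types × 2 hemispheres × 6 biological
replicates. Everything upstream of the count matrix (read QC, alignment,
counting) and everything downstream of the gene lists (pathway enrichment,
figures beyond the UpSet-style plot) is out of scope.

## Differential expression

The built-in test is a deliberately transparent negative-binomial Wald
test; users who prefer a full DESeq2-style fit can ingest its output table
(`ingest_external_de`), since the downstream binary transformation only
consumes (log2FC, adjusted p).

1. **Normalization.** Median-of-ratios size factors per cell type: the
   reference is the per-gene geometric mean over that cell type's samples,
   computed on genes with no zero count; each sample's factor is the
   median ratio to the reference. When no zero-free gene exists the
   library-size fallback (library size / mean library size) is available
   but must be enabled explicitly — it silently changes the normalization
   model, so it is opt-in.
2. **Dispersion.** Per gene and group, the moments estimator
   α = max(10⁻⁸, (s² − m)/m²) on normalized counts; the two hemisphere
   groups are pooled by a replicate-count-weighted average. At n = 6 the
   raw estimator's sampling noise dominates the Wald standard error, so an
   empirical-Bayes moderation step shrinks each gene's estimate toward the
   across-gene median with prior weight `dispersion_prior_df` (default 10,
   the residual degrees of freedom; 0 disables). This mirrors the
   dispersion-shrinkage practice of the standard count-based DE tools.
3. **Wald test.** log2FC = log2((m_ipsi + c)/(m_contra + c)) with
   pseudocount c = 0.5 on the normalized group means, keeping induced and
   shut-down genes finite. The per-group SE of the log mean is
   √(1/(n·m) + α/n) (delta method for a negative-binomial mean, variance
   m + αm²); groups combine in quadrature, convert to log2, and the
   statistic is referred to the standard normal (default) or a t with
   n₁ + n₂ − 2 df. The normal reference is the convention of count-based
   Wald tests; the t alternative is more conservative at the 0.05 level
   but its heavy far tail starves multiple-testing-corrected power when
   true effects are sparse (measured null rejection at nominal 0.05:
   0.063 normal, 0.035 t, both within expectations for n = 6).
4. **Multiple testing.** Benjamini–Hochberg step-up, applied within each
   cell type separately (one contrast per cell type). Implemented
   directly; cross-checked against statsmodels' `fdr_bh` in the tests.
5. **Significance.** |log2FC| ≥ 0.585 (fold change 1.5) and adjusted
   p ≤ 0.05, both inclusive ("minimum" fold change, "maximum" p).
   All-zero genes are untestable: log2FC = 0, p = 1, never significant.

A note on scale invariance: multiplying every sample's counts by one
common constant is *not* absorbed by median-of-ratios factors (the ratios
are scale-free), so the constant lands in the normalized means and the
absolute pseudocount shifts log2FC by a small amount — deeper data
legitimately carry more information. What is exactly invariant, and what
the property test asserts, is per-sample depth rescaling with unit
geometric mean.

## Binary transformation

Per gene and cell type: expressed-in-a-hemisphere = raw reads strictly
greater than `min_reads` (default 10) in **every** replicate of that
(cell type, hemisphere) group; regulated = DE-significant AND expressed in
at least one hemisphere. Expression calls use raw reads because the
threshold is defined in reads; a switch allows normalized counts for
sensitivity analysis. Genes absent from a cell type's matrix carry zero
bits there. The regulation bit is what demotes a gene that passes the DE
criteria in all four cell types but dips below the read threshold in a
single replicate outside one of them — the canonical demotion case drops
from the all-four category to the single-cell-type induced category.

Per-cell-type status: shut down (expressed contra only, log2FC < 0),
induced (ipsi only, > 0), down-/upregulated (both hemispheres); the four
classes partition each cell type's regulated genes. A regulated gene with
log2FC exactly 0 (possible only via external ingest) is left
not_regulated: its direction is undefined.

## Intersections and taxonomy

Genes are grouped by their exact 12-bit pattern (cell-type-major order:
contra-expressed, ipsi-expressed, regulated for EC, PC, AC, MG), i.e.
UpSet's exclusive intersections; 4096 patterns are possible, empty ones
are omitted, and the all-zero pattern is kept internally as a "none"
record so the records provably partition the gene universe (it is dropped
from exports). Records sort by count descending, ties by pattern key.

The 17 named categories map names to exact patterns; matching is strict
(the named bits and no others), the only reading consistent with the
demotion behavior above. A "definitional" mode (constraints only on the
bits a name mentions, most-specific name wins) is available behind a flag.
The regulated-only view groups by the four regulation bits alone
(≤ 16 patterns; all four = "EPAM-regulated") and is a provable coarsening
of the full grouping. Both counts are reported, since an expression filter
is embedded in the regulation bit and the two views legitimately differ.

Exports: the binary-table CSV interleaves, per cell type, the three bit
columns with mean reads and log2FC (the analysis-facing schema); the
UpSet-tool export writes the 12 bit columns as one contiguous block
followed by the meta columns, with a JSON descriptor (file name, separator,
header row, binary set column range, meta columns) in the public UpSet
web tool's convention — a contiguous set block is what that format
requires.

## Synthetic data

Counts are drawn from a negative binomial parameterized by (mean m,
dispersion α), variance m + αm², via the gamma–Poisson mixture — the same
model the DE stage assumes (self-consistency over realism). Defaults
emulate the assumed study design: 6 replicates per group, 10,000
background genes with log-uniform baseline means on [1, 5000], α = 0.1,
log-normal per-sample library factors (sd 0.2), planted |log2FC| = 2
(well above the 0.585 cutoff). Planted categories: 10 commonly upregulated
("epam") genes, 5 each per cell type of up/down/induced/shutdown, 3
opposite-direction genes, 20 markers per cell type.

Chosen magnitudes: planted expressed genes sit at mean 200 reads, where
the per-replicate probability of falling to ≤ 10 reads is negligible even
for a low-depth sample, so expression calls are stable; the silent side of
induced/shutdown genes sits at mean 0.5, below the threshold regime, with
the expressed side at mean 100. Induced/shutdown genes therefore have a
true log2FC set by their means (≈ ±7.6), not the generic ±2 — a mean of
0.5 cannot both quadruple and cross the read threshold. Markers leak at
mean 0.05 into other cell types, exercising asymmetric expression without
making genes literally absent.

What the simulator does **not** emulate: batch effects, gene–gene
correlation, length/GC biases, per-gene dispersion trends (optional
log-normal jitter only), or single-cell structure. Passing recovery tests
therefore show the pipeline's logic is correct under its own model, not
that the DE stage matches a full DESeq2 analysis on real data (a small
fixture-level agreement test against DESeq2 is included separately).

Recovery evaluation maps pipeline outputs back onto the planted
vocabulary (EPAM label → epam; exactly one regulated cell type → its
status category; two opposite-direction cell types → opposite; no
regulation and one expressed cell type → marker; otherwise background),
then reports per-category sensitivity, precision and the confusion table.
Boundary blur is expected and reported honestly — e.g. a "down" gene whose
ipsilateral reads dip below threshold in one replicate is recovered as
"shutdown".

## Outcome quantification

* **Volumetry**: each 2 mm TTC slice is imaged on both faces; every face
  area contributes a 1 mm-thick volume, summed over faces (default). The
  alternative reading — average the two faces, scale by the 2 mm slice —
  is available as a flag; with symmetric faces the two coincide. SV =
  V_infarct × (1 − (V_ipsi − V_contra)/V_contra); V_edema = V_ipsi −
  V_contra. SV ≤ V_infarct whenever there is swelling, with equality at
  zero edema.
* **Permeability**: pe = (B − bg)/(T − bg). Background correction is
  subtraction of the blank-well reading from both chambers — the standard
  reading of "corrected for background"; a negative corrected bottom
  clips to 0 with a warning, T ≤ bg is an error.
* **TEER**: series are rescaled so the value at treatment start is 100 %;
  the treatment-start value may be linearly interpolated from the
  bracketing pair (higher-order schemes rejected for transparency).
  Percent-of-control divides normalized treated by normalized control at
  each requested timepoint.
* **Staining intensity**: binary-mask area × mean intensity within the
  mask; the overlap variant multiplies the between-channel overlap area by
  the mean intensity of the channel of interest.
* **qPCR**: ΔCt = Ct_target − Ct_housekeeping per condition; a
  non-amplifying target's ΔCt is capped at 15; ΔΔCt = ΔCt_test −
  ΔCt_reference; relative expression 2^−ΔΔCt. A non-amplifying
  housekeeping gene is an error (normalization impossible).

Units are carried as conventions (mm²·mm → mm³; identical fluorescence
units within a tracer record); no automatic unit conversion is attempted.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; there is no global random
state, and rerunning a pipeline configuration reproduces every artifact
checksum (the run manifest excludes only the creation timestamp). The
test suite and the acceptance script run the simulator at its default
scale (≈ 10,200 genes × 48 samples) for the recovery and calibration
checks and at a 200-gene fixture scale elsewhere; both complete in
seconds on one CPU.

## Known limitations

* The built-in DE test is a moments-based Wald test; it does not reproduce
  DESeq2's shrunken fold changes, independent filtering or outlier
  handling, and deposited DESeq2 results are not expected to be exactly
  reproducible by any reimplementation.
* BH is applied within cell types; no across-cell-type FDR statement is
  made.
* The expression call is a hard threshold on raw reads; it inherits the
  depth-dependence of that rule (a gene can change call purely through
  sequencing depth).
* Named-category semantics are strict-exclusive; analyses wanting
  superset semantics must opt into the definitional mode.
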