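# Methods

## Scope and pipeline

`cnevolve` re-implements, as a tested library plus narrative analysis
scripts, a multi-sample tumor-evolution workflow: pseudo-CGH copy-number
profiling from paired tumor/normal read counts, BAF support at germline-het
SNP sites, changepoint segmentation, event classification with subclone
fractions, somatic SNV clonality, and cross-stage integration yielding a
linear-vs-parallel progression verdict. Alignment, variant calling engines,
functional annotation and survival association are out of scope; the filters
those tools feed are implemented exactly.

## Copy-number model

A sample is a mixture of normal cells (fraction `1 − p`) and tumor clones
with disjoint population fractions summing to the purity `p`. A clone
inherits all ancestral events; the *carrier fraction* of an event is the
share of all cells carrying it (`p·f`, with `f` the fraction of tumor
cells). Expected window copy is `2(1−p) + Σ_clones fraction·(c_A + c_B)`
with per-haplotype copies accumulated along the lineage.

The log2 track is `log2(n_tumor/n_normal)` per window, median-centered.
The expected value for copy state `c` is
`log2((2(1−p) + p((1−f)·2 + f·c))/2)`; the calibration points are 0 for
diploid, 0.58 for a clonal 3:2 gain and −1 for a clonal 1:2 loss. The median
is taken genome-wide (the signal is a single vector), excluding under-filled
terminal windows and zero-tumor windows (floored at −5 so plots stay
finite).

**Diploid re-baselining.** Median centering fails when altered territory
holds the median. The track is segmented, and segments of ≥ 50 windows with
≥ 10 informative SNPs whose *depth-debiased* allelic imbalance is < 0.03 are
collected; segments are grouped by mean log2 (tolerance 0.1) and the group
with the largest total window count is taken as diploid, its weighted mean
subtracted. Two deliberate choices here:

* the imbalance statistic is `sqrt(max(0, mean[(baf−0.5)² −
  baf(1−baf)/(depth−1)]))` rather than a raw median of |BAF − 0.5|, because
  at 60–100× the binomial noise floor of the folded statistic (≈ 0.67·σ ≈
  0.04) exceeds any sensible ε for truly balanced sites;
* the *heaviest balanced log2 level* is preferred over the single longest
  balanced span, because a long homozygous loss also shows BAF ≈ 0.5 (only
  the admixed normal cells retain alleles) and would hijack a longest-span
  rule in heavily rearranged genomes — exactly the regime the correction
  exists for. In the bundled metastasis-like scenario the correction shifts
  the baseline by ≈ +0.46 and truth-diploid windows then average 0.

## BAF model

BAF = B/(A+B) at known-SNP sites that are germline-heterozygous and covered
≥ 30× in both tumor and normal. When the germline genotype is not given, the
het call is a normal BAF in [0.25, 0.75] at qualifying depth (the exact het
window is a package choice, not an upstream fact). Orientation follows the
germline genotype, so imbalance is measured on the folded BAF |baf − 0.5|,
using the same debiased estimator per segment. Expected split under a het
loss: minor `= (1 − p·f)/(2 − p·f)`; balanced states (no event, balanced
gain, and the survivors of a subclonal homozygous loss) stay at 0.5.

## Segmentation

Exact penalized least-squares changepoint detection (the PELT recursion with
pruning) on a Gaussian-mean cost, hand-implemented; minimum segment length
10 windows, matching the 10-probe minimum per call. Default penalty
`3·σ̂²·log n` per chromosome with σ̂ from the median absolute successive
difference — a BIC-flavored default chosen for determinism; the upstream
segmentation engine this stands in for is proprietary and its sensitivity
settings are unknowable, so exact parity is not attempted. Segmentation is
invariant to adding a constant; abutting segments with |Δ mean| < 0.1 and
agreeing BAF states are merged (idempotent). Joint log2+BAF segmentation
(union of breakpoints, min-length enforced) is available; the pipeline
default segments log2 and annotates segments with BAF, which proved
sufficient at the study depths.

## Event classification

Loss candidates are segments below −0.1, gains above +0.15 (config-exposed).
Gains are graded on the purity-adjusted log2 (the value a clonal event would
show at purity 1): CG [0.15, 0.55), HCG [0.55, 1.0), VHCG [1.0, 1.8), EHCG
≥ 1.8 — invented defaults, since the source vocabulary never quantifies its
grades. Gains carry no clonality verdict (coverage cannot separate a clonal
moderate gain from a subclonal amplification).

For losses, `p·f` comes from the BAF inversion `(1 − 2m)/(1 − m)` with the
log2 inversion `2 − 2^(L+1)` as a cross-check (the two agree within 0.1 on
called het losses); clonality compares `f = p·f / p` against 0.8. A segment
whose implied het-loss `p·f` exceeds the purity by > 0.1, or whose
purity-adjusted depth is ≤ −2.5, must be homozygous (HL), with
`p·f = 1 − 2^L`. Note the stored `est_fraction` is the all-cells share
`p·f`; the "complete ⟹ fraction ≈ 1" intuition holds for `f`, not `p·f`,
whenever purity < 1.

Two-level losses: the non-HL loss means are split by exact two-class 1-D
clustering; two levels are accepted at ≥ 0.25 log2 separation, the deeper
cluster is level 2 (complete), the shallower level 1 (subclonal). A level-2
loss with folded BAF < 0.1 is re-resolved as subclonal HL (`p·f = 1 − 2^L`)
— the coexisting subclone retains both alleles. OCL (one-copy loss within
previously amplified territory) requires cross-sample context and is
assigned after per-sample calling, when a loss interval lies inside an
earlier stage's gain with a grade drop ≥ 0.3; the boundary between
whole-arm "LOH" rows and "OCL" in the source vocabulary is undefined, so
this rule is an interpretation and is confined to its own pass.

## Somatic SNVs

The discovery filter applies the documented thresholds verbatim: normal
depth ≥ 10 and normal BAF < 0.02; ≥ 3 alt reads **and** BAF > 0.15 in at
least one tumor sample; presence per sample at BAF > 0.05; known population
SNPs with AF > 1% excluded. Candidate generation upstream of the filter is a
plain per-site alt-count table (the original caller is not re-implemented).
Indels are treated like SNVs. VAF densities use a Gaussian KDE with
Silverman bandwidth; modes are peaks with prominence ≥ 10% of the maximum;
variants overlapping any copy-number event are excluded first, and < 5
usable variants yield no mode count. Purification bands default to
[0.05, 0.25] early and [0.35, 0.55] late, bracketing the reported subclonal
(~10–15%) and clonal (~40–48%) ranges.

## Progression integration

Events match across samples when chromosome and loss/gain class agree and
both breakpoints fall within `bp_tol` (0 for pre-tabulated tables, 2 window
widths for pipeline output); matching is one-to-one, nearest-first.
Mb totals sum tabulated rows without merging overlaps — this reproduces the
published per-sample loss totals (786.27 / 876.05 / 1014.93 / 1902.27) and
the first three gain totals (99.14 / 148.29 / 213.08) exactly. The published
metastasis gain total (239.55) is **not** reproducible from the table by row
summation (293.94) or territorial union (245.42); the package reports the
row sum and records the discrepancy rather than guessing the original
overlap rule. Two table rows also carry printed lengths inconsistent with
their own coordinates (flagged by the reader as warnings); printed lengths
are used for totals. Subclonal and complete presence both count as present.
In the molecular-time table, a later row duplicating an earlier gain's
coordinates (a further amplification of the same territory) is not counted
as a newly acquired region.

## Synthetic cohort (study conditions)

The default scenario mirrors the studied progression: four samples over a
7-clone tree — trunk clone A (clonal everywhere), DCIS-2 subclone B with a
private side branch B2, invasive clone C, metastasis-founder D (carrier 0.20
in the primary, 0.9 in the metastasis — the purification signature), the
metastasis trunk E, and a catastrophic subclone F (carrier 0.45) adding 17
shallow level-1 losses plus one homozygous loss whose depth coincides with
the clonal het-loss level at BAF 0.5. Purities are 0.8 / 0.8 / 0.8 / 0.9
(the pathology floor for these samples was 75% malignant cells). SNV counts
per clone (23 shared, 1 DCIS-2-private, 17 metastasis-private, 5 founder)
reproduce the reported membership pattern. The genome is miniature (5 × 40
Mb, 50-kb windows, 0-based half-open); defaults are 1000 reads/window
(matching the normal-read window definition; exome mean coverage only
brackets this, so it is a free parameter), 4000 SNP sites at 80×, variant
tables at 300× (validation-like depth). Noise is Poisson for counts and
binomial for allele depths, overdispersion off; all draws flow from a single
seed and are byte-reproducible.

What the simulator does *not* emulate: GC/mappability waves, FFPE artifacts,
sequencing error in the matched normal, read-level data, indels, and CNV-SNV
interaction (simulated SNVs sit in copy-neutral territory). Passing tests
therefore demonstrate correctness of the inference chain under the stated
noise model, not robustness to platform artifacts real exomes add.

## Numerical choices and degenerate inputs

Zero-normal windows are dropped with a warning; zero-tumor windows floored
at −5 and excluded from the median. A chromosome with < 20 windows is a
single segment. `expected_log2` of total copy 0 returns −inf. BAF folds
> 0.5 are clipped with the estimate saturated at `p·f = 1`. Empty call sets,
single samples (trivially linear) and query sets with zero Mb (concordance
undefined, reported as such) are all handled explicitly. Ties in two-level
clustering fall to a single level; a lone loss is level 2.

## Problem sizes

Default analyses use the miniature genome (4000 windows, 4 samples), a
20-scenario purity × fraction recovery grid at 1000-read windows, and
55-variant cohorts — sizes chosen so the full study, including the
acceptance checks, runs in well under a minute on one core while every
recovered quantity (breakpoint recall, Mb totals, `p·f` error, pattern
counts) has comfortable statistical margin.

## Known limitations

Single-patient-style analysis; no genome-wide allele-specific integer copy
fitting, no phasing, no tree inference beyond the two-subclone-per-sample
structure the two-level method resolves, no formal chromothripsis test, no
gene-level annotation. The linear-vs-parallel verdict is a *consistency*
statement about event nesting at the assay's resolution, not proof of
clonal ordering.
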