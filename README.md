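# cnevolve

Multi-sample tumor genome-evolution analysis: coverage-based pseudo-CGH
copy-number profiling with B-allele-frequency (BAF) support, aneuploidy-aware
baseline correction, changepoint segmentation, subclone-fraction estimation,
somatic point-mutation clonality tracking, and megabase-concordance
classification of **linear versus parallel** metastatic progression.

The package is aimed at cancer-genomics analysts who have successive lesions
from one patient — e.g. pre-invasive lesions (DCIS), the primary tumor and a
later metastasis, each exome-sequenced with a matched normal — and want to ask:
*did the metastasis descend late from the most advanced primary clone (linear
progression, perfectly nested event sets), or did it disseminate early and
evolve independently (parallel progression, with events private to earlier
samples)?*

## The model

**Pseudo-CGH.** The genome is cut into windows each holding a fixed number of
reads in the matched normal (1000 by default). Per window the tumor/normal
count ratio is log2-transformed and the vector is centered on its median:
a diploid window sits at 0, a clonal single-copy gain (3:2) at 0.58, a clonal
heterozygous loss (1:2) at −1. For a copy state *c* carried by a fraction *f*
of tumor cells at purity *p*,

```
log2 ratio = log2( (2(1−p) + p((1−f)·2 + f·c)) / 2 )
```

so normal admixture and subclonality compress the signal toward baseline.
When altered territory holds the coverage median (aneuploidy), the baseline is
re-anchored on segments whose germline-heterozygous SNPs show balanced allele
fractions (BAF ≈ 0.5).

**BAF support.** At germline-het known-SNP sites covered ≥ 30× in tumor and
normal, BAF = B/(A+B). A heterozygous loss carried by the fraction *p·f* of
all cells moves the minor BAF to `(1 − p·f)/(2 − p·f)`, which inverts to

```
p·f = (1 − 2m) / (1 − m)        (m = minor BAF)
```

with the coverage-based inversion `p·f = 2 − 2^(L+1)` as a diagnostic.
Two discrete log2 loss depths ("level 1" subclonal vs "level 2" complete)
with matching BAF splits reveal coexisting subclones; a level-2-deep loss
whose BAF stays at 0.5 is a *homozygous* loss confined to one subclone
(`p·f = 1 − 2^L`). Gains are graded (CG/HCG/VHCG/EHCG) but never receive a
clonality call — a moderate clonal gain and a strong subclonal amplification
are indistinguishable in coverage.

**Progression.** Per-sample event sets are matched across stages (same
chromosome, same loss/gain class, breakpoints within tolerance); the verdict
is *linear-consistent* iff every earlier-stage event is retained in every
later stage. Concordance between samples is Mb-weighted; per-event
acquisition stages give the molecular-time ordering.

**Somatic point mutations** pass the standard discovery filter (normal depth
≥ 10, normal BAF < 0.02, ≥ 3 alt reads and BAF > 0.15 in ≥ 1 tumor sample,
presence at BAF > 0.05, population SNPs > 1% excluded); membership patterns,
"purification" (subclonal early → clonal late, pinning the metastasis founder
to a primary subclone) and copy-neutral VAF densities summarize clonality.

A clone-tree simulator (`cnevolve.simulate`) generates every input the
pipeline consumes — paired window counts, SNP allele depths, multi-sample
variant tables — with exact truth tables, so the whole chain is testable
without patient data.

## Worked example

The bundled `data/progression_events.tsv` is a published four-sample event
table (two DCIS regions, primary tumor, asynchronous metastasis; 95 events).

```
$ python analysis/01_event_table_progression.py
Progression verdict: linear-consistent

  DCIS 1: 99.14 Mb gained (11 events), 786.27 Mb lost (25 events)
  DCIS 2: 148.29 Mb gained (16 events), 876.05 Mb lost (28 events)
  Primary tumor: 213.08 Mb gained (25 events), 1014.93 Mb lost (34 events)
  Metastasis: 293.94 Mb gained (43 events), 1902.27 Mb lost (52 events)

Concordance vs DCIS 1 (Mb-weighted):
  DCIS 2: 86.44%
  Primary tumor: 72.10%
  Metastasis: 40.32%
```

Every earlier-stage event is retained downstream and none is private to an
earlier sample — the nested structure expected under linear progression, with
72.10% of the primary tumor's event megabases already present in the first
pre-invasive lesion. (The metastasis gain total is a plain row sum; see
`docs/methods.md` for a documented discrepancy in the source table.)

The same can be driven from the CLI (`cnevolve progression --table ...`), and
`analysis/02`–`05` run the full synthetic-cohort study: simulation, copy-number
pipeline scoring against truth (breakpoint recall 100% at the default depth,
totals within 0.1 Mb), subclone-fraction recovery (median |p·f| error ≈ 0.008
over a 20-scenario purity/fraction grid), and SNV clonality (pattern counts
23/17/1/0, five purified founder variants, unimodal DCIS-1 vs bimodal primary
VAF densities).

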