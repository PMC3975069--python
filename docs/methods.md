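# Methods

## Scope and model of the data

`cagecompare` treats a transcriptome readout as a two-stage process: a
*capture* stage that samples molecules from an expression profile with
platform-dependent weights, and a *reporting* stage that maps each
captured molecule to an aligned coordinate with platform-dependent
displacements. Everything downstream (quantification, reproducibility,
mixing, diagnostics) operates only on the reported coordinates plus
library-level metadata, exactly as it would on real aligned data.

Simulation works at the level of aligned coordinates plus a recorded raw
leading base. Base-calling errors and the alignment step itself are not
modelled: mapping-quality and identity filters act upstream of every
quantity the package computes, so simulating them would add parameters
without adding testable structure.

Coordinates are 0-based, half-open throughout. "Upstream" and
"downstream" are strand-aware (upstream of a minus-strand TSS is
`tss + 1`); the sense-strand sequence of a minus-strand gene is the
reverse complement of the forward genome.

## The synthetic reference

`generate_reference` lays genes left to right on one chromosome with at
least 1 kb spacing, drawing per gene a strand, a length, an exon count
and a GC target uniform over [0.30, 0.70]; the gene's neighbourhood is
generated at that GC composition so promoter GC (±500 bp around the
TSS) and exonic GC form a controlled covariate. Strata are then planted:

- 25% of genes receive a sense-strand `CTGCTG` (an EcoP15I `CAGCAG`
  site on the antisense strand) at a random offset ≤ 400 bp downstream
  of the TSS, and 15% at an offset in (400, 800];
- 10% of genes start with a genomic T run of length drawn in [4, 15]
  (runs at other TSSs are truncated below 4 so planted and unplanted
  genes are cleanly separated);
- 5% of genes are histone-like (non-polyadenylated), and one ribosomal
  gene is appended.

Accidental `CTGCTG` occurrences in the scanned window are scrubbed
before planting, and **every stored context field is recomputed from the
emitted sequence**, so stored values agree exactly with the FASTA — a
property the test suite asserts, and the reason diagnostics can be
graded by exact recovery.

## Platform models

A `PlatformModel` bundles the distortion parameters. The capture weight
of gene *g* for CAGE is

```
w_g = a_g · f(base at TSS) · exp(b·(GC_g − 0.5)) · k^[antisense site ≤ 400 bp]
```

with `a_g` the molar abundance, `f` the linker first-base preference,
`b` the natural-log GC coefficient and `k ≥ 1` the EcoP15I boost. After
multinomial capture, each read passes two transforms in order:

1. **G addition** with probability `g_add_prob` (preset 0.87, the rate
   reported for reverse transcriptase): if the strand-aware upstream
   genomic base is G the aligned 5′ end extends 1 bp upstream
   (indistinguishable from a templated start); otherwise the mismatching
   leading G is recorded and trimmed, leaving the position unchanged —
   the same convention real pipelines apply to 5′ mismatches.
2. **Fill-and-lock T-run displacement** (single-molecule preset): a read
   starting inside a TSS T run of length ≥ 4 is reported at the first
   base past the run.

A `jitter_frac` fraction of reads initiates at tss ± 1 to give CTSS
peaks realistic single-base shape; with jitter and all mechanisms off,
every read reports exactly its gene's TSS (asserted as the
truth-conservation property). Ribosomal reads are injected at a rate
drawn once per replicate from a truncated normal — per replicate, not
per read, so replicate-level variability in the unintended-signal
fraction is reproducible. RNA-seq fragments take 5′ ends uniform over
spliced exonic coordinates (length 35 bp, clipped at the 3′ end), weight
`exp(b·(exonic GC − 0.5))`, and survive polyA selection with probability
`polya_escape_rate` when non-polyadenylated.

Preset magnitudes that the underlying study reports only qualitatively
(first-base weights G:1.3 / C:0.6, GC coefficients −1.5 and −1.0,
EcoP15I boost 1.5) are free parameters chosen to reproduce the
qualitative ordering (G-start overestimation, C-start underestimation,
PCR-platform GC dependence, near-site overestimation); diagnostics are
validated against whatever value is planted, not against a constant.

## Quantification

CAGE tags aggregate to CTSS tables (exact per-position counts;
ribosomal reads excluded and carried separately, so totals are
conserved). Gene counting uses a **closed ±500 bp window** around the
TSS — the distance at which the promoter-capture curve
(`tss_distance_profile`) saturates. A position inside several windows is
assigned to the nearest TSS, ties to the lexicographically smallest gene
id; this prevents double counting and is deterministic. RNA-seq
fragments count for a gene when they overlap any exon by ≥ 1 bp,
unstranded by default (a strict-strand mode is a flag); multi-gene
overlaps resolve by nearest exon start, then smallest id.
Normalisations are tags-per-million (`count/library·1e6`) and RPKM; the
library size is the total of mapped non-ribosomal reads, so TPM columns
sum to 1e6 times the assigned fraction.

## Reproducibility metrics

Pairwise Spearman uses midranks over genes nonzero in at least one of
the two samples; it rises with depth, which is why the package also
reports a depth-independent metric: the **relative standard error**,
√φ̂ of a common negative-binomial overdispersion
(`Var = m + φm²`). φ̂ maximises the likelihood *conditional on each
gene's total count* (golden-section search on [1e−6, 1], tolerance
1e−6), which removes the unknown gene means; a profile likelihood with
plug-in means is biased low by roughly a factor (n−1)/n at n = 3
replicates, so the conditional form is used. Conditioning assumes
near-equal library sizes across replicates — true for technical
replicates sequenced to the same depth, and exactly what the simulations
produce; the estimate is invariant to uniform library rescaling. Genes
with mean count < 5 are dropped (configurable): they carry almost no
dispersion information and destabilise the fit.

## Mixing and the effective ratio

Mixtures are composed in **mass** space (`compose_mixture`), but
sequencing measures **read shares**: with mass ratio `r` and
quantifiable fractions `qA`, `qB`, pool A contributes
`r·qA/(r·qA+(1−r)·qB)` of the quantifiable reads. `synthesize_mix`
therefore mixes *normalized* profiles linearly, and
`estimate_effective_ratio` grid-searches α ∈ {0, 0.01, …, 1} minimising
the mean squared M (`log2` ratio with pseudocount 0.5 TPM; genes below
an A threshold excluded, default none) between the synthetic mix and
the observed profile, ties to the smaller α. The mean-squared-M scalar
is this package's formalisation of "closest match" between MA plots;
for noiseless inputs on the grid, recovery is exact, and the objective
is numerically convex.

## Bias diagnostics

All ratio diagnostics use tags-per-million with pseudocount 0.5 and
report **medians** per stratum (robust to the heavy-tailed per-gene
ratios), restricted to genes detected in both profiles.

- *GC*: equal-width bins (default 10) over the observed GC range plus a
  least-squares slope of per-gene log2 ratio on GC; a planted
  natural-log coefficient `b` on one platform appears as slope `b/ln 2`.
- *EcoP15I*: genes classified `none` / `antisense_le_max` /
  `antisense_gt_max` by scanning 0–800 bp downstream of the TSS for
  sense-strand `CTGCTG`; the reported contrast (near-site median minus
  no-site median) approaches `log2 k` for a planted boost `k`. The
  far-site class is emitted as an extra stratum without a quantitative
  claim.
- *Start base*: per-base median log2 TPM ratio at positions with ≥ 5
  tags in both tables; recovers the planted ordering G > A ≈ T > C.
- *T-run shifts*: a reference position with enough tags whose
  sense-strand sequence begins with a T run of length L ≥ 4 is flagged
  when the other table has tags L bp downstream but none at the position
  itself; totals are reported over all examined reference positions, so
  the fraction is comparable to a genome-wide shifted-TSS rate.
- *Smoothing*: a (2h+1)-base moving average (default h = 1, i.e. 3-base)
  conserves total signal and rescues the single-base Spearman between
  platforms that disagree by ±1 bp.
- *Platform-exclusive TSSs*: candidates have **strictly more than** 10
  tags in at least one table; an exclusive call is "unneighbored" when
  the other platform has no position with ≥ 3 tags within ±20 bp (the
  neighborhood width is a config; the threshold semantics — strict
  "more than 10", inclusive "three or more" — follow the conventional
  phrasing of such filters).

The G-addition estimator restricts to TSSs whose start base *and*
upstream base are both non-G: there a raw leading G can only be the
artifact, so the G-leading fraction estimates the addition probability
directly and without bias.

## Sample comparison

Clustering ranks genes by mean expression, keeps the top 8000 (or all,
with a warning), and applies average linkage to `1 − Spearman` —
invariant to monotone per-sample transforms. Clade support is the
fraction of B gene resamples (with replacement, same size) whose tree
contains the same clade: an ordinary bootstrap, chosen over multiscale/
approximately-unbiased corrections because the testable claims here are
topological and the ordinary bootstrap already stabilises them. The
differential test is a Wald-style NB approximation: condition totals
compared on the log scale with standard error
`sqrt(1/ΣxA + 1/ΣxB + 2φ̂)` (pseudocount 0.5, φ̂ pooled from the
replicated conditions, 0 with a warning when none are replicated) and
Benjamini–Hochberg control. Using φ̂ per condition side regardless of
replicate count makes the test conservative for n > 1, which the type-I
simulations confirm; power on 4-fold changes at moderate counts remains
essentially complete.

## Problem sizes and what the tests show

Default study conditions mirror the benchmark: mixture panels at ratios
100:0, 99:1, 95:5, 90:10, 50:50, 0:100; quantifiable fractions 0.84
vs 0.36; dispersion recovery on 10,000-gene triplicates at 2,000,000
reads; replicate Spearman on 20,000 genes at φ = 0.01. The bundled demo
and the test suite run smaller references (40–300 genes, 10⁴–10⁵ reads
per sample) — large enough for every recovery band while keeping a full
run in tens of seconds.

Passing tests demonstrate that each estimator recovers what the
generator plants under the generator's assumptions. Real data differ in
ways the generator deliberately omits: no alignment or sequencing-error
model, no PCR duplicates, single-G (never multi-base) nontemplated
addition, a deterministic full-run T-stretch displacement rather than
partial fills, an effect-level (not mechanism-level) EcoP15I model, and
no unannotated transcription beyond a scalar quantifiable fraction.
Recovery here validates the *estimators*; absolute bias magnitudes on
real libraries must still be measured, not assumed.

## Known limitations

- The common-dispersion fit assumes near-equal library sizes; strongly
  unequal replicate depths would need a quantile adjustment it does not
  implement (no tagwise or trended dispersion either).
- The differential test is intentionally simple and conservative; it is
  not a replacement for a full GLM framework on real designs.
- CTSS-level diagnostics assume both samples come from the same genome
  build and strand conventions; there is no liftover or annotation
  reconciliation.
- The CLI's `demo` is a fixed analysis circuit; bespoke studies should
  compose the library functions directly (see `examples/`).
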