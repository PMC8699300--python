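# Methods

## Design objects

A locus is an amplicon insert (genomic sense strand, primers included, no
barcodes) with 1-based CpG positions indexed 1..n in 5'→3' order. The
bundled demo design uses the published primer sequences, insert lengths
(GSTP1 142 bp, RNF219 161 bp, KIAA1539 89 bp), CpG counts (17/17/5) and
the X1–X8 / Y1–Y12 8-mer barcode lists; the insert cores between the
primer footprints are **synthetic stand-ins** (the true amplicon sequences
are not published), fabricated deterministically so that the declared CpG
positions are the only CG dinucleotides and the primer footprints are
conversion-invariant (they contain no cytosine on the sense strand). Which
amplicon end carries the X codes is a per-locus property (X on the reverse
primer for GSTP1/RNF219, on the forward primer for KIAA1539).

The demo barcode assignment gives each of the 55 samples one (X, Y) pair,
with the PCa and HD groups drawing from disjoint code subsets so that a
tumor/healthy cross-over can never produce a valid pair; the 41 unused
pairs of the 96-pair grid define the chimera set.

## Synthetic cohort model

Each (group, locus) is a finite mixture of epiallele classes — per-CpG
methylation probability vectors with weights summing to 1. The default
calibrated model uses deterministic classes:

| Locus | Class | HD | BPH | PCa |
|---|---|---|---|---|
| GSTP1 | fully methylated | 0.16% | 0.16% | 8.35% |
| GSTP1 | methylated at {3, 13, 16} | 0.1% | 10% | 1% |
| RNF219 | fully methylated | 0.13% | 0.003% | 0.13% |
| RNF219 | methylated at 1–8 | 0.07% | 0.002% | 0.07% |
| KIAA1539 | fully methylated | 1% | 1% | 1% |

with the unmethylated background absorbing the remainder. The weights are
calibrated to the published group-level anchors: GSTP1.C9 ≈ 8.35% in PCa
vs ≈ 0.16% elsewhere; RNF219 pairwise-CC frequencies ≈ 0.005–0.02% in BPH
vs ≈ 0.13–0.21% elsewhere with separation cutoffs in the ~0.05% regime;
GSTP1.T3.T13 ≈ 99.5% in HD vs ≈ 88.5% in the pooled tumor groups; and no
group differences at KIAA1539. `EpialleleModel.expected_variable` returns
the exact pre-noise expectation of any variable under the model, which the
tests use as the law-of-large-numbers reference.

**Per-sample dispersion.** The within-group variance of patient-level
variable values is not published. The generator multiplies every
non-background class weight by an independent lognormal(0, σ) factor per
sample (default σ = 0.3, i.e. roughly a ±2.5× range at 3σ — consistent
with the published spread between group means and the most extreme
boundary values). Because the real cohort's dispersion is unknown, the
printed per-patient sensitivities and CV metrics are not reproducible;
recovery of the qualitative separation structure is the claim the tests
make.

**Noise.** Three independent per-base Bernoulli processes: conversion
failure (a non-CpG cytosine stays C; default 0.01), inappropriate
conversion (a methylated CpG reads T; 0.005), and sequencing substitution
(0.001, uniformly to a different base). Only the conversion-rate filter
threshold is published; these defaults are the simplest process that
exercises it. Chimeric reads (default 1%) receive a uniformly drawn
unused barcode pair. Coverage is uniform on 5,000–20,000 reads per
sample×locus — scaled down from the published 23,509–143,953 to keep
desk-scale runtimes while preserving the regime where 0.01–0.2% patterns
are detectable. Quality strings are constant; qualities only break ties
in pair merging.

**Detection-limit consequence.** At 5,000 reads a 0.13% pattern averages
~7 molecules, so an occasional non-tumor sample draws zero copies of an
RNF219 pattern carried only by the rare fully-methylated class. A zero in
the non-BPH pool ties with the (mostly zero) BPH samples and breaks
complete separation for that pair, which is why the acceptance surface for
the BPH screen is: all 136 CC pairs screen-significant, with complete
separation on the well-covered (~0.2%) marker pairs. At the published
coverage every expected count is ≥ 30 and this failure mode vanishes.

The generator also has a fast path (`simulate_pattern_tables`) that draws
pattern counts directly without read-level noise — used for calibration
studies over many cohorts (e.g. the 100-run null control) — and a WGBS
mode (`simulate_wgbs_reads`) emitting short fragments at uniform offsets
so each read covers only a CpG subset. The WGBS tissue model mixes fully
methylated molecules at 51.8% (normal) and 79.9% (cancer), the positive
fractions observed for GSTP1.C9 in the screened public prostate datasets;
fragment length defaults to ~100 bp and 40 fragments per sample (the
published medians).

**What the generator does not emulate:** PCR duplicates/jackpotting,
cycle-dependent error profiles, cfDNA fragment-length structure,
per-patient covariate structure (PSA is simulated independently where
used), and the real cohort's dispersion. Passing tests therefore
demonstrate correctness of the machinery and qualitative recoverability of
calibrated effects, not clinical performance.

## Read processing

Reads are merged full-amplicon sequences: 8-bp barcode, forward primer
footprint, converted insert, reverse primer footprint, reverse-complement
barcode. Demultiplexing tries both orientations, requires the primer
footprints to match with ≤ 2 mismatches, and matches the terminal 8-mers
exactly; outcomes are mutually exclusive dispositions with precedence
UNASSIGNED > CHIMERA > CONVERSION > UNRECOGNIZED, so the input read count
always equals retained + Σ exclusions.

Methylation calling uses a gapless per-position comparison against the
in-silico converted reference (amplicons are fixed-length), falling back
to a global alignment (match +1, mismatch −1, gap −2, CpG positions
wildcarded to {C,T}; identity floor 0.7) when the insert length differs or
the non-CpG mismatch fraction exceeds 10%. At each CpG: C → methylated,
T → unmethylated, anything else or a gap → unrecognized. The conversion
rate is the fraction of *alignable* reference non-CpG cytosines read as T;
the retention rule (rate ≥ 0.95, boundary inclusive, and no unrecognized
site) is applied per read. Only the bisulfite top strand is modeled — the
amplicon primers define a single converted strand.

## Variables

Per locus: n single-position variables (`GENE.Ci`) and 4·C(n,2) joint
variables in deterministic order (singles by position, then pairs
lexicographic by (i, j, status) with statuses CC, CT, TC, TT). All
variables at a locus share one denominator — the sample's retained read
count — because reads with any unrecognized site were excluded upstream.
Single-T variables are not enumerated (they equal 1 − Ci and would double
count the family); the parser still accepts `GENE.Ti` in model formulas
and resolves it to 1 − `GENE.Ci`. Proportions are kept as exact
count/total pairs alongside floats so that separation cutoffs compare tiny
proportions without float ties. Samples with no retained reads at some
locus are dropped with a logged warning.

## Statistics

**Exact Mann–Whitney.** Mid-ranks for ties, doubled to integers; the null
distribution of the rank-sum over all C(n, n₁) assignments is computed by
the shift-algorithm dynamic program and cached per tie pattern. The
two-sided p is the null probability of a rank sum at least as far from its
null mean as observed (distance from the mean — not a doubled one-sided
tail). Counts stay below 2⁵³ for cohort sizes, so float64 arithmetic is
exact. Adjustment is Bonferroni ×(3·1167), capped at 1; covariates such
as PSA run through the identical machinery but never enlarge the family.

**Separation metrics.** All thresholds in both orientations (the positive
group may sit high or low), computed on exact rationals. Complete
separation means some threshold attains 100% sensitivity and 100%
specificity; then the cutoff is the geometric mean of the two closest
cross-group values (arithmetic mean if one is zero; the larger/smaller
ratio is reported only when both are nonzero). Otherwise the cutoff is
the midpoint threshold maximizing sensitivity + specificity (first-found
on ties, scanning low to high, high-orientation first).

**LOOCV logistic regression.** Class-balancing weights w_g =
N_train/(2·n_g,train), recomputed inside each fold (equal total weight per
class, no leakage). Fitting is IRLS with fold-local standardization,
iteration cap 100, deviance tolerance 1e-8, and coefficients capped at
±30 on the standardized scale so separable training folds saturate
instead of diverging. Held-out probabilities are classified at 0.5;
accuracy/sensitivity/specificity are unweighted proportions over the
held-out predictions. If any single predictor completely separates the
full data, all CV metrics are reported as 100 without fitting. The
single-predictor path is vectorized across folds; tests verify it against
a per-fold statsmodels GLM fit.

**DeLong AUC.** Mann–Whitney statistic with ties counted ½; variance by
the structural-components estimator; Wald interval truncated to [0, 1] and
omitted when AUC = 1 (it is always (1, 1) there).

**Forward selection.** Greedy on LOOCV accuracy, ties broken by higher CV
AUC and then canonical variable order; stops at `max_predictors` (default
3) or when no addition improves accuracy.

**WGBS screen.** A read is evaluable for a variable iff it covers all the
variable's positions; present iff every position matches the specified
status (other covered positions are ignored). Reads pool across samples
into the normal/cancer groups. Pearson chi-square without continuity
correction when all four expected counts are ≥ 5, else the conventional
two-sided Fisher exact test (sum of tables at most as probable); a zero
margin reports p = 1 with a degenerate flag. Adjustment multiplies by the
locus's own enumeration size (561 for 17 CpGs), capped at 1.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full cohort at the
generator's default scale (55 samples × 3 loci × 5,000–20,000 reads,
~2 million reads end to end, about a minute on one CPU); the 100-cohort
null-calibration study uses the direct pattern-count path. On null
cohorts the screen's false-positive count is zero in ≥ 99 of 100 seeded
runs — the exact test plus the ×3501 Bonferroni family is strongly
conservative at these sample sizes.

## Known limitations

Only the sense strand and exact 8-mer barcode matches are modeled (no
barcode error correction); the conversion-rate denominator follows the
per-read "alignable non-CpG cytosines" reading, which the original
calling software may define differently; triple-and-higher joint variables
are out of scope, as are regularized classifiers and multiple-testing
procedures other than Bonferroni. The WGBS mode consumes per-read call
tables; alignment of real WGBS data is out of scope.
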