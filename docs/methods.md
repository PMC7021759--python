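# Methods

This note documents the models and procedures implemented in `nblandscape`,
the parameters that matter, the numerical choices, and what the synthetic
generators do and do not emulate.

## Reproducible peaks and the reference set

Each sample carries two peak sets from the same caller: a high-confidence
set (strict FDR, nominally 0.05) and a low-confidence set (permissive FDR,
nominally 0.5). Within a genotype group, a sample's high-confidence peak is
*reproducible* if it overlaps (≥ 1 bp) a low-confidence peak of at least one
**other** sample in the group. The "at least one" reading is a design
choice: with two replicates per group, "any other" and "every other"
coincide, and "any" generalizes to larger groups; `support="all"` selects
the stricter reading. A group of one sample is refused rather than silently
passed through — the rule is undefined there.

The reference peak set is the merged union of the three groups'
reproducible sets. Merging uses strict overlap: abutting intervals
(`a.end == b.start`) are *not* merged, because half-open intervals that
touch share no base. A reference peak's `present_in` flags record which
groups' reproducible sets overlap it.

## Fragment counting and the moderated differential test

A fragment counts if its length is strictly below 2000 bp; it increments
every reference peak it overlaps, with no multi-hit correction (a fragment
spanning two merged peaks contributes to both). The library size used for
normalization is the number of size-passing fragments in the sample, not
the in-peak total.

Differential occupancy between ATRX and each other group is tested on
log2 counts-per-million with pseudocount 0.5:
`log2((count + 0.5) / (libsize + 1) * 1e6)`. Each contrast is a two-sample
comparison whose pooled residual variance s² (df = n₁ + n₂ − 2) is shrunk
toward an empirical-Bayes prior: a scaled inverse-chi-square distribution
fitted by moment matching on log s² (digamma/trigamma moments, with a
Newton inversion of the trigamma function). The moderated t statistic uses
the posterior variance and df = d₀ + df_residual; p-values are two-sided
and BH-adjusted per contrast. This is a defined moderated test in the
limma/voom family, *not* a reimplementation of voom: voom's mean–variance
precision weights are deliberately out of scope, and no numeric equality
with that tool is claimed. Calibration is verified empirically: on null
Poisson counts (3 vs 3 samples, 500 peaks, 20 seeds) the raw p ≤ 0.05 rate
is ≈ 0.049, inside the nominal band.

## C/E/D/O classification

The default mode is purely presence-based, because the group definitions
are presence/level statements with no stated thresholds: C = present in all
three groups, E = ATRX only, D = MYCN and WT but not ATRX, O = ATRX plus
exactly one other group; anything else (single non-ATRX group, empty) is
`unclassified`, so labels always partition the reference set. The
`presence+stats` mode additionally demands, for E and D, BH-adjusted
p ≤ 0.05 in both contrasts and a direction-consistent log fold change
(ATRX-higher for E, ATRX-lower for D); peaks failing the statistical gate
drop to `unclassified` rather than being relabelled.

## Annotation rules

* **G4 / RLFS.** A peak is G4-flagged if it overlaps any G4-motif interval;
  the R-loop fraction is reported *among G4-flagged peaks* (matching how
  these tracks are conventionally summarized), so
  `n_g4_rlfs ≤ n_g4 ≤ n_peaks` always. An empty G4 track reports both
  fractions as 0 with an `undefined` flag.
* **Dominant state.** The chromatin state covering the most bp of the
  interval; ties break to the lowest state number; uncovered bp are
  ignored; a fully unsegmented interval yields an explicit `None`.
* **State concordance.** Default rule (`disjoint`): the dominant states of
  peak-present samples and peak-absent samples must share no state.
  Alternative (`active_class`): present samples must sit in active or
  enhancer class states and absent samples in inactive-class states. Peaks
  present or absent in *all* samples have no contrast and are excluded
  (`None`), as are peaks unsegmented in any sample.
* **Location.** Promoter if the peak overlaps [TSS − 2 kb, TSS + 2 kb) of
  any gene — symmetric and strand-agnostic; otherwise enhancer if the
  dominant state in any peak-present sample is enhancer-class; otherwise
  other. Only the state-13 expansion metric uses a strand-aware
  *downstream* window [TSS, TSS + 2 kb), since it measures spread of a
  transcription state into the gene body: a gene is expanded when the
  state-13 bp fraction satisfies `prop_plus > 2 × prop_minus` and
  `prop_plus ≥ 0.20` (the floor is inclusive).
* **18-state class map.** Only part of the state semantics is fixed by the
  upstream model (states 1–4 active euchromatin, 13 strongly transcribed
  gene body, 15–17 inactive heterochromatin, 18 CTCF). The enhancer states
  (5–7 here) and the remaining "other" states are a declared package
  convention, overridable per `Segmentation` via `state_classes`.
* **DMR association.** DMR validity gates: length ≥ 50 bp, ≥ 3 CpGs,
  |methylation difference| ≥ 0.2, caller p ≤ 0.01. A valid DMR is
  associated with a gene when it overlaps [TSS − 1 kb, TSS + 1 kb) and the
  gene is differentially expressed (|log2 FC| ≥ 1, adjusted p ≤ 0.1).

## Clinical statistics

`fisher_two_tailed` is the standard two-sided Fisher exact test by
point-probability summation (sum of hypergeometric point probabilities no
larger than the observed table's), not tail doubling — summation reproduces
the published cohort values that doubling does not. `chi_square_test` is
Pearson's chi-square without continuity correction. `select_test` picks
Fisher when any expected count is below 5 **or** any observed cell is zero,
chi-square otherwise; the zero-cell trigger reflects standard practice for
sparse tables where the asymptotic test is anti-conservative. `cmh_test`
(Cochran–Mantel–Haenszel, via statsmodels) uses no continuity correction;
on a single stratum it equals the Pearson chi-square scaled by (N−1)/N.
Clopper–Pearson intervals come from beta quantiles, with the conventional
closed endpoints lower = 0 at k = 0 and upper = 1 at k = n.

The packaged cohort fixture stores per-classification margins (level,
total, mutants) rather than one joint patient table: each classification
had its own denominator in the source cohort (not every assay was applied
to every tumor), so a single patient-level table consistent with all
margins at once is over-constrained. `simulate_cohort` expands any margin
list into a patient-level table with exact counts.

## Drug-screen scoring

Concentrations follow the screening geometry: top concentration
stock/890 (the pin-tool transfer), then nine further 1:3 dilutions (10
points per compound). Normalization is on the log2 RLU scale. Cytotoxic
mode maps the plate's control *means* exactly to vehicle = 1 and positive
control = 0; protective mode subtracts the mean log2 vehicle signal, so a
doubling of raw signal adds exactly 1.

The dose–response fit is a cubic smoothing spline in log10 concentration
with the penalty chosen by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`). Replicates are pooled into one
fit: tied concentrations are averaged with weight equal to the replicate
count, which yields the identical penalized least-squares solution.

The protective AUC evaluates the fitted curve on a fixed 256-point uniform
grid over [min x, max x], takes the baseline as the **fitted** value at the
lowest concentration (robust to noise in the single lowest-dose well,
which a raw-datum baseline is not), and integrates the positive part of
(curve − baseline) by the trapezoid rule. Units are (log10 concentration) ×
(log2 RLU). A numerical guard zeroes excess below 1e-10 so exactly flat
curves score exactly 0. Because the original screen's smoother defaults are
unknown, equality with any previously reported per-compound AUC values is
not claimed; the metric is validated against dense-grid quadrature of known
generating curves (≤ 1% error for a well-resolved bump) and by separation
of planted bumps from no-effect noise.

## Synthetic-data generators

`plant_landscape` places non-overlapping peaks (default 1000 peaks of
400 bp on a 3 × 1 Mbp genome, ≥ 2.5 kb apart so no two loci ever merge and
no locus falls into another's promoter window) and assigns labels
(C/E/D/O = 30/15/40/15%, D largest), G4 flags (35%), RLFS flags (70% of G4
peaks), and locations (30% promoter, 30% enhancer). The group design is
three groups × two replicates, mirroring a six-cell-line panel. These
defaults are the study conditions the generator emulates; the 1000-peak
genome is a desk-scale stand-in for a genome-wide reference set of tens of
thousands of peaks.

`simulate_peak_landscape` then derives everything per sample: jittered
high-confidence peaks at present loci (default jitter ≤ 20 bp/edge),
low-confidence peaks as ±100 bp padded highs plus Poisson low-only decoys,
fragments at present peaks (Poisson, mean 20 per peak) over uniform
background (0.2 fragments/kbp) with lengths from a clipped normal
(mean 250, sd 300, clipped to [50, 4000] bp), segmentations that tile each
chromosome with a background state and switch to an active (or enhancer)
state over present loci and an inactive state over absent loci, G4/RLFS
track intervals centered on flagged peaks plus decoys placed ≥ 2.5 kb from
every peak, and a TSS table with genes at promoter-planted peaks plus
distant decoy genes. All randomness flows through one seeded generator per
bundle, so a fixed seed gives byte-identical written outputs.

What the generator does **not** emulate: real replicate-to-replicate peak
jitter statistics (unknown; jitter is a free parameter), read-level noise
and mappability artifacts, copy-number-driven coverage bias,
non-independent peak placement (clustering at CpG islands), fragment-length
mixtures with a genuinely heavy >2 kb tail, and partially penetrant state
shifts. Passing the recovery tests therefore demonstrates the pipeline's
correctness on its own contract — that the rules recover exactly what was
planted — not its robustness to every artifact of real chromatin profiling
data.

## Problem sizes in the tests and acceptance script

The shipped checks use 40–1000 planted peaks, 20 × 500-peak null
simulations and single 96-well plates; these sizes make the full suite run
in seconds while keeping every statistical check (binomial 99% intervals,
type-I bands) meaningful at its stated tolerance.

## Known limitations

* The moderated test assumes roughly constant within-group variance on the
  log-CPM scale; it inherits no mean–variance trend modelling, so very low
  count peaks are tested slightly conservatively.
* `presence+stats` mode with two replicates per group has limited power;
  with the default enrichment it demotes few peaks, but users with more
  replicates should prefer it.
* The CMH mutual-exclusivity test is implemented and tested for statistical
  correctness, but per-stratum counts of the original multi-cohort analysis
  are not published, so its exact p-value there cannot be reproduced.
* Survival modelling (Cox, Kaplan–Meier) is intentionally out of scope.
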