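# Methods

## Overview

`nucleoflow` implements a flow-cytometric counting and sizing analysis for
nuclei isolated from frozen unfixed postmortem cortical gray matter, of the
kind used to compare neuronal (NeuN+), oligodendroglial-lineage (olig2+) and
other (NeuN−/olig2−) nuclei densities between psychiatric case and control
groups in two regions (frontopolar cortex, FPC/BA10; inferior temporal
cortex, ITC/BA20). Because no raw event data of this design are publicly
deposited, the package pairs the analysis with a synthetic event-level
cohort generator that supplies ground truth for every stage; all
calibration and power claims in the test suite are claims about that
generator, not about any archived specimen.

## Measurement model

Each sample is an event list with forward scatter (FS, integer 0–1023) and
three fluorescence channels (7-AAD DNA, NeuN, olig2).

**Counting beads.** A known quantity of bright, uniform beads is co-measured
with the aliquot. The ratio of nuclei events to bead events converts event
counts to absolute numbers:

    N_total = (nuclei events / bead events) × beads added
    density = N_total / tissue mass        [nuclei per mg]

Class densities are `density × class proportion`, so the class partition
(NeuN + olig2 + double-negative = total) is conserved exactly by
construction.

**DNA-line gating.** Intact nuclei sit on two 7-AAD intensity lines: G0/G1
at I0 and G2/M at 2·I0. Beads are gated first (intensity above a configured
multiple — default 5 — of the median); I0 is then the mode of the smoothed
log-intensity histogram of the remainder, the line CV is estimated from
events within ±20% of I0 (clamped to [0.005, 0.2]), and nuclei are events
within `tolerance × CV` (default tolerance 3) of either line. Everything
else below the lines is debris. G2/M nuclei are counted as nuclei of their
marker class; their doubled DNA plays no role in class assignment.

**Marker thresholds.** With the default `"auto"` setting, the NeuN and olig2
cutoffs sit at the first substantive valley to the right of the
lowest-intensity (unstained) mode of the smoothed log-intensity histogram.
The first valley, not the deepest, is used because the olig2 distribution
can be trimodal (negative / weak / strong). This makes gating invariant to
a uniform rescaling of the fluorescence axes and to event order. An event
passing both marker thresholds is assigned to NeuN (a fixed, arbitrary rule;
the generator never produces such events, and their count is reported as a
warning).

**olig2 weak/strong decomposition.** A two-component Gaussian mixture is fit
to log olig2 intensity (EM, scikit-learn, fixed random state). Two peaks are
"detectable" when the lighter component holds ≥ 0.10 of the mass and the
means are ≥ 2.0 pooled within-component SDs apart; otherwise the sample
contributes to olig2 totals but is excluded from weak/strong comparisons,
mirroring the subgroup design in which only samples with two clearly
measurable peaks enter that analysis. Events are hard-assigned by posterior
responsibility; the reported boundary is the geometric midpoint between the
adjacent assigned intensities. Non-convergence flags the sample
undetectable rather than raising.

## Nuclear-size analysis

NeuN+ nuclei with FS ≥ 400 are excluded: above that point the apparent size
is inflated by incompletely removed perinuclear material (the microscopy
cross-check places the equivalent boundary at ~200 µm² of traced NeuN
area). The retained population is adjusted to a fixed total of 10,000.
The default adjustment multiplies the integer FS counts by a common factor
and keeps fractional counts (deterministic, conserves the total to
round-off); seeded subsampling without replacement is available because
either reading of "adjusted population" is defensible. Twenty-one
overlapping windows [n, n+99], n = 100..300 in steps of 10 (closed
intervals on integer FS), are each compared between groups with an
unpaired pooled-variance t-test. No multiplicity correction is applied
across the 21 windows by default — the windows are strongly correlated and
the procedure is reported per window — but a Holm-adjusted column is
available. Fixed-range count tests (defaults FS 101–199 and FS 251–349,
following the main-text ranges rather than the slightly different
supplementary-figure labels) support the postmortem-interval scenario.

## Cohort statistics

* **Group tests** — unpaired two-sided Student t (pooled variance; Welch by
  flag); one-way ANOVA for three or more levels. Percent differences are
  computed on group means, `(mean_case − mean_control)/mean_control × 100`,
  matching the convention of quoting group-level contrasts.
* **Confounder screen** — Pearson r of each class density against age,
  refrigeration interval, PMI, pH, brain weight and frozen-storage days;
  flagged at p < 0.05, uncorrected (the screen is deliberately liberal).
  Flagged covariates enter an OLS ANCOVA `density ~ group + covariates`;
  the type-II group term is the adjusted test. With nothing flagged the
  plain t-test is passed through. Collinear or constant covariates are
  dropped with a warning.
* **Exclusion-matched reanalysis** — samples with PMI > 40 h or
  refrigeration interval > 20 h are dropped (strict inequality: a sample
  exactly at the threshold is kept) and the density and window analyses are
  rerun.
* **Asymmetry** — each subject contributes one hemisphere, so the asymmetry
  index is computed on group means: `mean(L)/mean(R) × 100 − 100` (positive
  = left greater). Group differences in asymmetry use a two-factor
  factorial ANOVA (group × hemisphere); the interaction term is the
  designated asymmetry-difference statistic, because "the left/right
  pattern differs between groups" is an interaction claim, and the group
  main effect is reported alongside. Residual df is N − 4 for the 2 × 2
  design.
* **Disease-only covariates** — onset age, disease duration and
  fluphenazine equivalent are screened on diseased samples only; gender,
  hemisphere and abuse severity (binarized at the median) are tested by
  unpaired t-test.

## Synthetic cohort generator

The generator emulates the study design: per-region group sizes
(FPC 12/12/10, ITC 12/11/11 for control/BPD/SCH), ~20 mg gray-matter
samples, one hemisphere per subject (balanced within groups), a measured
aliquot fraction of 1%, and 10,000 counting beads per aliquot (≈100 bead
events). Absolute levels are **not** published for this design, so the
baseline total density (100,000 nuclei/mg) and the class partition
(NeuN 0.45, olig2-weak 0.07, olig2-strong 0.05, double-negative 0.43) are
explicit configuration defaults chosen to be biologically plausible for
human neocortical gray matter — they are documented as arbitrary and are
never asserted as published values.

Per-sample true densities are the baseline times configured multiplicative
effects (per diagnosis × region × class), an optional left-hemisphere
asymmetry multiplier, a shared between-subject lognormal factor (CV 0.25 by
default, parameterized to mean exactly 1), an independent per-class
lognormal jitter (CV 0.10), and optional linear covariate links. Event
counts are Poisson at `density × mass × aliquot fraction`. Small-NeuN
disease effects reduce the small-component weight of the NeuN FS mixture
(small: FS 240 ± 45; large: FS 470 ± 80; small weight 0.55) with the large
weight compensating, so total NeuN density is unchanged — reproducing the
observed "small-nucleus deficit without total neuronal loss" pattern.
The 7-AAD channel has a 3% line CV and a 2% G2/M fraction at doubled
intensity; marker channels are lognormal with well-separated negative /
positive (and weak/strong) modes; debris (5% of expected nuclei events)
sits below the DNA lines; beads are 50× brighter than I0 with 1% CV.

**Postmortem FS drift** is multiplicative, `FS ← FS × (1 + δ·PMI)`, so
larger nuclei shift more in absolute FS units; δ defaults to 0.1/48 per
hour — calibrated (arbitrarily, and documented as such) so a 48 h PMI moves
peaks by ~10%. A per-sample lognormal FS scale jitter (CV 3%) models
instrument drift between acquisitions.

**Rat PMI preset.** The rat scenario uses a NeuN FS mixture with its
dominant small component at FS ≈ 128 (σ 45, weight 0.85) and a minor large
component at FS ≈ 600. Under a multiplicative shift, the count in a fixed
FS range is first-order invariant when `a·f(a) ≈ b·f(b)` at the range
endpoints; placing the dominant peak so that FS 101–199 satisfies this
makes the small-range count insensitive to the drift while the tail range
FS 251–349 responds strongly — the qualitative pattern in which postmortem
delay inflates apparent nuclear size without changing nuclei numbers, and
only the larger-size range reaches significance with n = 4 per group.

**Microscopy pairs.** Traced 7-AAD areas are the FS mixture mapped linearly
at 0.5 µm²/FS (so FS 400 ↔ 200 µm²); NeuN areas add a perinuclear
inflation term (slope 0.15 above 200 µm²) plus tracing noise (SD 25 µm²),
chosen so the paired-area Pearson r at n = 200 falls in the low 0.9s,
bracketing the correlation observed with real material.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes — Poisson
counting, bead calibration, class mixtures, DNA lines, PMI drift, covariate
distributions and configurable effect/asymmetry/link patterns. It does not
model cytometer optics or spillover/compensation, doublets beyond the DNA
lines, cortical lamination, correlated sampling of the two regions from the
same subjects, or non-lognormal biological heterogeneity. Passing tests
therefore certify the pipeline's correctness and calibration under these
idealized conditions, not the biological conclusions of any real cohort.

## Numerical choices and degenerate inputs

* Histogram mode/valley finding uses 128 log-spaced bins smoothed with a
  Gaussian kernel (σ = 3 bins); peaks below 2% of the maximum are ignored
  and a valley must dip below half of the flanking peaks.
* Scaled FS counts stay fractional (no integer rounding), so adjusted
  totals are exact to |Δ| ≤ 0.5 and window sums conserve mass.
* Empty event tables, missing channels, absent bead events, all-excluded FS
  lists, empty design cells and empty exclusion remainders raise typed
  errors (`DataError`, `CalibrationError`, `GatingError`); an all-debris
  sample (everything below the configured debris floor) returns zero counts
  without raising.
* An unidentifiable olig2 two-peak fit is a flag, not an exception.
* Determinism: every stochastic step draws from `numpy` generators seeded
  via `SeedSequence` children of the run seed; equal seeds give
  byte-identical datasets and report bundles.

## Problem sizes used in the shipped checks

Effect-size recovery runs 100 replicate cohorts per contrast (12 vs 12
samples at ~20,000 nuclei and ~100 bead events each; 9 vs 9 for the
weak/strong contrast), which puts the Monte-Carlo error of the averaged
percent difference near 1 percentage point. Null calibration uses 500
cohorts for the window procedure (2,000 NeuN events per sample) and the
density t-test and 300 for the factorial ANOVA. These sizes were chosen so
the whole battery completes in minutes on a single core while keeping
binomial error well inside the asserted bands.

## Known limitations

* Absolute density levels are conventions, so only relative contrasts are
  meaningful acceptance quantities.
* The auto-threshold valley search assumes the unstained population is the
  lowest-intensity mode and that positive populations are resolvably
  separated; heavily overlapping stains would require explicit numeric
  thresholds.
* The bead gate assumes beads are a small minority of events and much
  brighter than the G2/M line.
* ANCOVA covariate selection inherits the screen's uncorrected α = 0.05,
  by design; it is a replication of a screening convention, not a
  recommendation.
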