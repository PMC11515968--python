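# Methods

## Scope and data model

The package analyzes nCounter miRNA panels: a codeset of endogenous
barcode probes plus six control classes (positive titration, negative,
ligation positive/negative, exogenous spike-ins, housekeeping mRNAs).
Counts travel through three explicit stages — `raw` (integers as scanned),
`background_subtracted`, `normalized` — and every operation declares which
stage it consumes. Detection is always defined on raw counts, because the
limit of detection is itself derived from raw negative-control counts;
normalization feeds only the expression-level analyses.

## Limits of detection

Negative-control counts are pooled over probes and lanes (one triplet per
dataset; a per-lane variant is available via `scope="per_sample"`):

* Low = geometric mean; zero counts are replaced by 1 before the log
  transform so the mean stays defined (log2 1 = 0).
* Medium = Low + 2·SD, where SD is the arithmetic sample standard
  deviation (n−1) of the pooled counts on the linear scale. Computing the
  SD on the log scale is a defensible alternative; the linear scale was
  fixed because the published triplets this rule reproduces (e.g. Medium =
  Low + 2·SD landing at roughly 1.7× Low for serum panels) behave like
  linear-scale dispersion, and the choice is documented rather than
  exposed as a hidden branch.
* High = exactly 2 × Medium; the class enforces this identity at
  construction, so no downstream consumer can hold an inconsistent triplet.

Detection uses strict inequality (count > Low). The prevalence rule "at
least 15% of samples" is implemented as `count ≥ ceil(0.15·n)` with a
1e-9 guard against binary-float excess (0.15 × 20 must give 3, not 4); a
plain fraction comparison is available as `rule="fraction"`.

## Normalization

Order of operations: background subtraction → positive-control scaling →
top-100 content scaling, the order nSolver applies them in.

* Background: per lane, subtract the geometric mean of that lane's
  negatives from every non-negative-class probe and floor at zero.
  Negative rows are carried through unmodified for audit.
* Positive factors: g_s = geometric mean of the six positive probes in
  lane s; factor = mean(g)/g_s. A zero g_s is an error naming the lane.
* Content factors: the 100 endogenous probes with the highest mean count
  across the full analysis set (never per group, to avoid group-biased
  scaling), ties broken by probe name ascending. Zeros inside the content
  geometric mean are replaced by 1 — a probe can rank into the top set on
  its mean yet be absent from individual lanes (group-restricted probes do
  exactly this). With fewer than 100 endogenous probes, all are used with
  a warning.
* Factors outside [0.3, 3] are flagged, never excluded; exclusion is the
  caller's decision.

All log transforms of counts use a +1 pseudocount, since zeros survive the
background floor.

A consequence worth knowing: content normalization partially absorbs
strong, widespread group effects. When many of the top-100 probes carry a
real fold change, the content factor removes part of it, attenuating the
estimated log2FC by roughly θ·(k/100) for k affected top probes at effect
θ. The recovery tests see this as a small systematic shrinkage (≈0.2 log2
units for 20 planted four-fold effects); with `skip_content=True` the
attenuation disappears.

## Differential expression

Welch's two-sided t on log2(count+1), vectorized over probes; log2FC is
the difference of group means on the same scale, so fold change and test
statistic share a definition. Benjamini–Hochberg values are always
reported, but volcano classification (up: log2FC > θ and p < α; down
mirrored; defaults θ = 1.5, α = 0.05) uses the raw p, matching the
published cutoff convention for this assay class. Probes with zero
within-group variance in both groups get p = 1 and a flag rather than an
exception.

An optional variance moderation shrinks each group's per-probe variance
toward the across-probe mean with `n_mod` (default 4) pseudo-degrees of
freedom, and credits those degrees to the Welch–Satterthwaite df. This is
a deliberate simplification of empirical-Bayes moderation: it stabilizes
small-n variance estimates without fitting a prior, and it is off by
default so the unmoderated test remains the reference behavior.

The treatment contrast runs in two stages: probes differential between
healthy and untreated patients (Welch, |log2FC| > θ, p < α), then
two-sided Mann–Whitney U of the treated stratum against each of the other
two. `recovered` = treated differs significantly from untreated *toward*
the healthy mean; `unchanged` = no significant treated-vs-untreated
difference; `other` = significant movement away from healthy. Degenerate
all-tied comparisons return p = 1 instead of a tie-correction NaN.

The isolation-method comparison is a paired t-test on per-patient
differences of log2(normalized+1). The phrase "Welch's t-test, paired by
the patient" from assay practice is contradictory; pairing is the stated
design, so the paired test is the default and an unpaired Welch variant
remains available through `de_test`.

## Clustering

Rows (probes) are z-scored (n−1 SD) on log2(count+1); constant rows become
all-zero and are flagged rather than dropped. Ward linkage follows the
ward.D2 convention — Euclidean input distances, squared inside the
criterion — via scipy's implementation; the test suite pins the convention
against an independent Lance–Williams implementation to 1e-9. Equal-height
merges resolve to the lowest pair index, so output is deterministic. The
exported contract is the ordered scaled matrix plus both linkage tables;
no cluster count is imposed, and heatmap rendering is out of scope.

## Enrichment

Over-representation of a target-gene query against GMT annotation sets:
hypergeometric upper tail P(X ≥ overlap) over the declared universe, fold
enrichment (query rate / universe rate), BH FDR across sets, significant
at FDR < 0.05. miRNA→target interactions arrive as two-column files; with
several prediction databases, only pairs present in all of them are kept
(the consensus-intersection rule). Target *prediction* itself is out of
scope — the package consumes interaction lists, it does not generate them.

## Synthetic data generator

The generator emulates the statistical structure of a two-method serum
cohort so every stage is testable without any download. All log-scale
parameters are base 2, the scale on which fold changes are analyzed.

Defaults and what they emulate:

* Codeset: 827 endogenous probes, 6 positive (128…0.125 fM four-fold
  titration), 8 negative, 3+3 ligation, 5 named spike-ins, 5 housekeeping.
* Cohort: manual 10 healthy / 5 untreated / 9 treated, automated
  12 / 4 / 7 (47 lanes), with 8 dual-method subjects (2 healthy, 2
  untreated, 4 treated) sharing patient ids, ages and genders across
  methods.
* Abundance: per-probe baseline 2^N(log2 20, 2.2) counts; per-observation
  noise 2^N(0, 0.5); per-lane scale 2^N(0, 0.2). These place lane totals
  in the tens of thousands and roughly 60–70% of probes above a ~16-count
  background at 15% prevalence — the regime the analysis is designed for.
* Background: negatives ~ Poisson(16); endogenous probes additionally
  carry Poisson(2) nonspecific counts. The endogenous background is set
  below the negative-control mean so that absent probes genuinely fall
  under the Low LOD; with equal means, roughly half of all absent probes
  would exceed a geometric-mean threshold by chance and "exclusive
  detection" would be meaningless.
* Effects: disease fold changes are planted on probes with baseline ≥ 128
  counts — a biomarker must be quantifiable above background for its fold
  change to be estimable after background subtraction. Treatment recovery
  removes the effect in the treated stratum for a configurable fraction of
  planted probes. Group-exclusive probes are present at 150 counts in one
  group and background-only in the other. Method effects are per-probe
  multiplicative capture offsets applied to manual lanes. Optional dropout
  zeroes endogenous counts at a stated rate.

A single seeded RNG stream drives everything; one seed yields a
byte-identical fixture suite, and the ground-truth ledger records exactly
which effects were injected.

What the generator does **not** emulate: sequence-level G/C capture-bias
mechanisms (method effects are free per-probe offsets, not
sequence-derived), within-subject correlation beyond shared demographics
(dual-method lanes draw independent counts, so the paired test sees pure
method effects without a subject random effect), cartridge/batch drift,
and real per-probe abundance distributions, which are unpublished — the
lognormal is an assumption. Passing recovery tests therefore demonstrate
that the pipeline's inference is correct under its own assumptions, not
that those assumptions capture every property of clinical serum data.

## Calibration and problem sizes

On a null fixture (827 probes, 10 vs 10 lanes, no planted effects) the
differential test's type-I rate at α = 0.05 sits inside the exact binomial
99% interval, and p-values are uniform for probes quantifiable above
background; probes hovering at the background floor are censored by the
max(·, 0) subtraction and show mild non-uniformity with a conservative
tendency, which is why prevalence filtering precedes testing. Recovery
checks use 20 planted four-fold effects at n = 10/group; invariant suites
run on 100 random fixtures of 25 probes × 12 lanes; round-trip checks use
the full 47-lane default cohort. These sizes keep the whole suite in the
seconds-to-minutes range while exercising every code path at the cohort
scale the design targets.

## Known limitations

* The differential engine is Welch-on-log2 with optional simple
  moderation, not a full empirical-Bayes linear model; fold changes come
  from one fixed definition (difference of log2 means), not from a fitted
  coefficient.
* Housekeeping probes are carried and reported but never used for
  normalization — the miRNA panel normalizes on positives and codeset
  content.
* Binding density and FOV pass bounds ([0.1, 2.25]; 0.75) are platform
  conventions, not study-derived, and are labeled as such in the QC
  report.
* RCC support targets the canonical plain-text lane dialect; vendor binary
  bundles and PlexSet/CNV variants are out of scope.
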