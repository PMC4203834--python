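# Methods

This note records the models, conventions and numerical choices behind
`platesort`, and what the synthetic-data studies do and do not show.

## Data model

One instrument record is an *observation*: well coordinate, integer sort
status, time of flight (TOF, instrument units; a proxy for object length),
integrated extinction (EXT) and integrated green/yellow/red fluorescence.
Wells follow the standard 96-well geometry: rows A–H, columns 1–12,
canonical labels unpadded ("A1" … "H12"), canonical order row-major.
TOF, EXT and fluorescence must be finite and nonnegative; normalized
channels (`norm_*`) and the bubble probability are missing until the
corresponding operation has run.

### File format and dialects

Instrument exports are flat tab-delimited text, but column headers vary by
firmware.  Parsing maps headers onto canonical fields through a
case-insensitive synonym table (`Col`/`Column`, `Extinction`/`EXT`,
`Status sort`/`Sort status`/`Status`, …), extensible at run time via
`register_synonym`.  TOF, EXT, Row and Column are required; anything else
is optional.  One file holds one plate; a `Plate` column is tolerated only
if constant.  Malformed lines — truncated, non-numeric or negative
required fields, invalid wells, duplicate object ids — are dropped and
counted in a per-file parse report rather than aborting, because real
instrument files frequently end mid-line.  Numbers use a decimal point
only.  On write, missing values are empty fields ("NA" is accepted on
read), floats use the shortest round-trip decimal representation, so
write→parse is the identity on all canonical fields.

## Filtering

**Cutoffs.**  TOF and EXT bounds are inclusive at both ends (a
user-specified limit naturally reads as "allow this value").  Records with
a missing value in a bounded channel fail the comparison and are removed.
Cutoff filtering is idempotent and equals a record-by-record filter by
construction.

**Bubble classifier.**  Air bubbles and precipitate are indistinguishable
to the instrument but separate from organisms chiefly on optical density
per unit length, so the default feature vector is (TOF, EXT, green,
yellow, red, EXT/TOF).  Training follows the two-plate protocol: all
records of a pure-organism plate labelled 0, all records of a pure-bubble
plate labelled 1.  Features are standardized by the training-set mean and
SD; the model is an RBF-kernel SVM (C = 1, scikit-learn's `gamma="scale"`).
Decision scores are mapped to probabilities by Platt scaling: a logistic
link fitted to 5-fold out-of-fold decision scores, so the calibration data
are not the scores the SVM was fitted on.  Held-out accuracy is estimated
on a stratified 20% split whose seed is user-settable and stored with the
model.  An object is flagged when P(bubble) strictly exceeds the threshold
(default 0.5); with threshold 1.0 nothing is ever flagged.  Classifiers
persist to a single self-describing JSON file (features, scaling, support
vectors, dual coefficients, Platt coefficients, threshold, seed), so no
binary pickle is involved and loading reproduces predictions exactly.
Models must be trained per device — internal parameters differ between
machines — so no pretrained model ships with the package.

Cutoff filtering and classification can run in either order; the CLI
applies cutoffs first.  In annotate mode classification commutes with
subsetting up to floating-point batch effects (≤ 1 ulp).

## Normalization and summarization

Integrated measures grow with object size, so each channel is divided by
TOF per object: `norm_ext = ext / tof`, likewise fluorescence.  Objects
with TOF = 0 get missing normalized values and are counted; original
columns are never modified.  The identity `norm_x · tof = x` holds exactly
wherever TOF > 0.

Per-well summaries report *n* (the well's record count) and, per trait,
mean, median, unbiased variance (n−1 denominator, missing when n < 2),
min, max and the 10/25/75/90% quantiles (configurable).  Quantiles use
linear interpolation between closest order statistics (the "type 7"
convention, numpy's default) — fixed and pinned by an oracle test, since
quantile conventions differ across software.  Missing values are skipped
per trait.  Log-transformed summaries use the natural log of strictly
positive values only; non-positive values are *excluded*, not shifted,
because an arbitrary pseudo-count would distort EXT distributions — the
per-well exclusion counts are kept alongside the summary.

Well removal supports two modes: `na` blanks every trait field (and *n*)
while keeping the row; `drop` deletes the row.  Removing an absent well is
a warning-level no-op.  `fill_wells` completes a summary to exactly 96
rows in row-major order with all-missing statistics for added wells; it is
idempotent and rejects duplicate wells.  Summarization is invariant to
observation order (to float summation order) and commutes with drop-mode
well removal.

Strain and dose metadata are 96-element vectors in row-major well order
A1…H12 (the plate-map convention); a `well,strain`/`well,dose` CSV is also
accepted by the CLI.

## Edge-effect test

Evaporation and oxygenation gradients hit the plate border hardest, so the
plate is split into the outer ring (rows A and H plus columns 1 and 12 of
rows B–G: 36 wells) and the 60 interior wells; `edge_depth=2` adds the
second ring (64 vs 32) for gradients that penetrate further.  Per trait, a
per-well summary statistic (default the well mean) is compared between the
two populations with a two-sided Wilcoxon rank-sum test.  Wells are the
exchangeable units; comparing pooled raw objects would pseudo-replicate —
thousands of objects per well would make trivial differences significant.

The rank-sum test: W is the first sample's midrank sum.  When
n₁ + n₂ ≤ 20 and the pooled sample is tie-free, the two-sided p is exact —
the null distribution of W is enumerated by dynamic programming over rank
subsets, and p = min(1, 2·min(lower tail, upper tail)).  Otherwise the
normal approximation is used with tie-corrected variance and a 0.5
continuity correction; zero variance (all values identical) yields p = 1.
The exact mode is verified against brute-force enumeration of all
C(n, n₁) assignments, and both modes against an independent rank-sum
implementation.  When testing all traits, untestable traits (all missing)
are reported, not fatal; raw p-values are reported by default, with an
optional Benjamini–Hochberg adjustment (off by default, since a screener
usually inspects per-trait p-values).

## Correlation and dose response

Trait correlations are Pearson over wells (Spearman by flag),
pairwise-complete: each trait pair uses exactly the wells where both
values are present, and entries with fewer than 3 complete pairs are
missing.  Within-plate matrices are symmetric with unit diagonal;
between-plate mode matches the two summaries by well and crosses the
first plate's traits with the second's.

Dose-response summarization attaches the strain and dose vectors to
wells, groups by (strain, dose), and reports each group's mean of the
per-well statistic plus the contributing well count; wells with a missing
value are excluded from their group (a fully missing group stays in the
table with count 0).  Each plotted point is one well's value — one
summarized observation — and lines connect group means across doses.  No
curve fitting (EC50/4PL) is done; the output is the raw mean-by-dose
profile.

## Visualization

Each figure family is a pure `prep_*` transformation into a plate-grid
layout (panels addressed by well, 8×12 geometry) plus a thin matplotlib
renderer, so everything quantitative is testable without touching pixels.
Histograms share one bin range across the plate (30 bins by default) so
panels are comparable; box plots use 1.5×IQR whiskers (the conventional
default).  Correlation matrices use a diverging red/blue scale centered at
zero; missing heatmap wells render as an explicit "no data" panel.  SVG
output is deterministic (pinned hash salt, no timestamp), so identical
inputs give byte-identical files.

## Synthetic plates

The generator emulates instrument files so the whole pipeline is testable
without hardware.  Default organism model, per well: TOF lognormal with
median 300 instrument units and object-level log-SD 0.15; a well-level
random effect (log-SD 0.05) creates realistic well-to-well variation;
EXT = 0.5·TOF·lognormal(0, 0.1) noise, giving the monotone TOF/EXT cloud
seen in real data; fluorescence gamma(2, scale 15/10/5).  Population sizes
are Poisson(30) per well.  Bubbles: TOF ~ N(40, 10), EXT ~ N(5, 2)
truncated positive, dim gamma fluorescence — short, optically thin
objects.  The two-plate training protocol draws the pure organism plate
from N(300, 30) TOF and N(150, 20) EXT, a separation where a nonlinear
boundary is easily found.  Edge gradients are additive shifts on edge-well
means, parameterized in SD units of the well-mean distribution, enabling
calibrated power studies; a strain×dose layout applies per-well
multiplicative effects on TOF and population size (four strains × five
doses by default, monotone inhibition).  Every draw derives from the
scenario seed; the same scenario yields byte-identical files.

**Study sizes.**  Calibration of the edge-effect test uses 1000 null
plates simulated at the well level (the well-mean distribution *is* the
test's sampling model, so per-object simulation would add nothing to the
type-I question) and 200 plates for power at a +5 SD gradient; oracle
sweeps for summaries, I/O and correlations use 100 random plates of ~6
wells × ≤6 objects, small enough that the pure-Python oracles stay exact
and the comparisons exhaustive.

**What passing does not show.**  The generator draws independent objects
per well; real plates have within-well clustering, instrument drift,
carry-over between wells and occasional double-object events, none of
which are modelled.  Classifier accuracy on the synthetic protocol says
the training/calibration machinery works, not that any particular real
device separates this cleanly — the per-device training protocol exists
precisely because real separations vary.

## Known limitations

- One plate per file; no plate stitching or FCS (cell-cytometry) format.
- The bubble classifier requires both training plates to share the
  features used; fluorescence channels absent from a plate are dropped
  from the default feature set but cause an error if requested explicitly.
- The edge-effect test compares per-well summaries, so plates with very
  few populated wells per population (< ~4 a side) have little power and
  the exact small-sample mode will engage.
- Correlation entries need ≥ 3 complete well pairs; sparse summaries can
  yield mostly-missing matrices.
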