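# Methods

This note documents the models, parameter choices, and numerical
conventions behind `gaitwalk`, and what the synthetic-data experiments
do and do not establish.

## Signal model and preprocessing

The raw input is a tri-axial accelerometer (m/s²) and gyroscope (deg/s)
stream from a lumbar-mounted IMU sampled at a fixed nominal rate
(100 Hz default), with cumulative walked distance known per sample. The
reader enforces strictly increasing time with inter-sample spacing
within 1% of nominal, a non-decreasing distance channel, and closed
material/age-group vocabularies. When a file carries no distance
channel it is synthesised as `t × speed` with a configurable constant
speed (default 1.3 m/s, inside the 1.2–1.5 m/s range reported for
adults on instrumented walkways). A note on units: published summaries
of accelerometer SVM are sometimes labelled "m/s"; physically the
quantity is an acceleration magnitude and this package treats it as
m/s² throughout.

Each stream is collapsed to its signal vector magnitude
`√(ax²+ay²+az²)`, which is invariant to sensor orientation changes and
is the only signal the rest of the pipeline consumes — no sensor fusion
or orientation estimation is attempted.

**Filtering.** The source methodology names only a noise-removing "SVM
filter"; the filter family is therefore an implementation choice,
stated here: a 4th-order Butterworth low-pass at 6 Hz applied
forward-backward (zero phase), with reflect padding at the edges so the
output keeps the input length and the first/last cycles are not
corrupted by transients. Nearly all gait energy in a lumbar SVM signal
lies below ~6 Hz, and zero-phase filtering leaves peak (cycle-boundary)
positions unshifted. A centred moving-average fallback is available.
Both are linear, so filtering and z-scoring commute in exact
arithmetic; the pipeline nevertheless fixes the order filter →
normalise.

**Normalisation.** Z-scoring is per recording (not per cycle), with the
population SD. The DTW scores are therefore in normalised SVM units and
comparisons are within-pipeline; see "Limitations".

## Segmentation

Cycle boundaries are successive prominent peaks of the processed SVM
series: prominence ≥ 0.5 × series SD, minimum separation 0.4 s. One
peak-to-peak interval corresponds to roughly one step of a
lumbar-mounted magnitude signal; the package does not attribute steps
to a foot and treats "cycle" as this peak-to-peak unit (source material
for this design does not distinguish step from stride). Cycles with
durations outside 0.4–2.5 s are dropped and counted in the log, not
merged — conservative, and any consistent boundary convention preserves
the comparative results the pipeline reports. Fewer than three
plausible cycles (including flat signals) is an "insufficient gait"
error.

## DTW core

Textbook dynamic programming over the local-cost grid with symmetric
unweighted steps {(1,0), (0,1), (1,1)} and absolute-difference local
cost (squared difference available). Absolute cost keeps distances in
signal units. Distances are raw path sums — not divided by path length
— because the downstream comparisons are between scores computed under
identical conventions; a path-length-normalised value is exposed on the
result object. Backtracking breaks ties diagonal-first, then vertical,
then horizontal, making paths deterministic. An optional Sakoe–Chiba
band (|i−j| ≤ r) exists but is off by default: cycles are < 300 samples
and the full grid is cheap. The inner recursions are numba-compiled;
the scoring path uses a two-row distance-only kernel.

The test suite checks the implementation against an independent
brute-force oracle that enumerates every admissible warping path on
short series, plus the identity/symmetry/non-negativity laws and the
Euclidean-upper-bound property. DTW is not a metric; no triangle
inequality is asserted anywhere.

## Reference cycles and aggregation

The "typical" cycle of a (material, age-group) stratum is its DTW
medoid. A medoid is deterministic given the tie-break (lowest candidate
index), robust to outlier cycles, and always an observed waveform. For
large strata the medoid is computed on a seeded order-preserving
subsample (default 40 candidates per stratum,
`max_reference_candidates`) — the medoid of a modest subsample is an
adequate "typical" cycle because cycles within a stratum are tightly
clustered. A global-reference mode
(`per_group_reference=False`) exists for sensitivity analysis.

Aggregation reports two statistics deliberately kept separate: per-cell
(material × age group × distance bin) mean/SD/min/max over individual
cycle scores, and per-(participant, material) mean scores. Cell SDs are
sample SDs (ddof = 1; population-SD flag available); a single-value
cell reports SD 0. Percent changes are `100 × (b − a)/a` at full
precision, rounded to one decimal only in reported tables; "X% lower
than" uses the larger value as the reference. Distance bins are
`floor(start_distance / 200 m)` clamped to the last bin, giving six
sections for a 1,200 m walk.

## ANOVA and descriptive statistics

One-way fixed-effects ANOVA with the textbook SS decomposition and the
upper-tail F p-value. `anova_from_ss` rebuilds a table from printed
sums of squares; mean squares always come from SS/df (one published
gyroscope mean square is inconsistent with its own SS/df while the
F-ratio is consistent, so SS/df is authoritative). The pipeline's own
ANOVA compares per-(participant, material) mean raw SVM across the four
materials — 4 groups × 80 participants, df (3, 316). Published tables
for this design show df (3, 76), implying 80 observations split across
materials despite every participant walking all four; that
between-subjects analysis can be reproduced exactly via
`anova_from_ss`, and neither analysis models the repeated-measures
structure (a deliberate non-goal). Quantiles use linear interpolation
(type 7), whiskers are Tukey's 1.5 × IQR convention, and histogram
counts conserve n. A seeded k-means on (accel, gyro) SVM feature pairs
is provided for exploratory material clustering only.

## Synthetic cohort generator

The generator emulates the study conditions: 16 participants in each of
five age groups (80 total), four materials, 1,200 m walks at 100 Hz.
Defaults:

| parameter | value | rationale |
|---|---|---|
| accel/gyro SVM mean, SD per material | wood 14.2/6.5, asphalt 15.7/7.1, concrete block 18.3/9.2, cement 19.1/9.5 (gyro 2.6/1.3, 2.5/1.2, 2.8/1.4, 2.9/1.5) | published per-material distributions |
| step period by age | 0.50–0.60 s (20–30 → 60+) | ~1.17–1.4 m/s walking speed at 0.7 m steps, matching reported adult/older-adult ranges |
| jitter_base per material | cement 0.096 > asphalt 0.050 > concrete block 0.034 > wood 0.010 | proportional to the published 200 m DTW levels |
| jitter_drift per material | 0.021–0.027 | proportional to the published 200→1,200 m DTW increments |
| age_gain | 1.0, 1.1, 1.2, 1.35, 1.6 | monotone fatigue-susceptibility increase with age |
| participant intensity SD | 0.10 | between-subject spread in movement vigour; gives a realistic material ANOVA instead of a degenerate one |
| measurement noise SD | 0.03 (normalised units) | small white sensor noise |

Each recording is a train of step cycles: a unit-variance stride
template (a dominant Gaussian impact pulse plus a broader secondary
pulse; pulse width shrinks mildly with material hardness) is
affine-mapped to the target SVM mean/SD, multiplied by a per-step
amplitude factor, and laid out over per-step periods with timing
jitter. Both jitters are Gaussian with SD growing **linearly** with
walked distance — `σ(d) = jitter_base + fatigue_drift × age_gain ×
jitter_drift × d/total` — the minimal model consistent with the
near-monotone DTW growth across distance sections that motivates the
method. Amplitude jitter is expressed per unit of the template's mean
absolute deviation so that a given σ produces the same expected
per-sample deviation (hence the same DTW level) for every material;
otherwise template spikiness would confound the calibrated ordering.
The scalar SVM is decomposed onto three axes by a fixed direction plus
slow angular wobble, so the axes reproduce the SVM exactly. All
randomness derives from one seed with per-recording counter-derived
substreams; identical spec + seed is bit-identical.

Two orderings are distinct by design: physical hardness (cement >
concrete block > asphalt > wood — drives template spikiness and matches
the published SVM-SD ordering) and gait-destabilising distortion
(cement > asphalt > concrete block > wood — drives jitter and matches
the published mean-DTW ordering). `distortion_ordering()` reports the
latter; it is the ground truth the recovery experiments test against.

**What the generator does not emulate:** biomechanically validated
waveforms, left/right asymmetry, rest pauses, turns, non-constant
walking speed, sensor drift or saturation, and any coupling between a
participant's intensity factor and their fatigue rate. Passing recovery
tests therefore show that the pipeline correctly extracts orderings and
distance trends from quasi-periodic signals with the stated
distributional structure — not that it would recover them from real
recordings, whose DTW magnitudes (tens of raw SVM units) are in any
case not reproducible from published summaries alone.

## Problem sizes and runtime choices

Recovery experiments (tests and `scripts/acceptance.py`) run the full
study design — 80 participants × 4 materials, six 200 m bins — with
`walk_scale = 0.12`: each recording simulates ~205 of the ~1,714 step
cycles of a full walk, uniformly covering the 1,200 m distance span
(~34 cycles per bin), which leaves the fatigue trajectory over distance
intact while keeping a 20-seed replicate set to a couple of minutes on
one CPU. The ordering-recovery check (≥ 19 of 20 seeds) and the
majority-vote bin-monotonicity check are evaluated at exactly these
sizes.

## Known limitations

* DTW scores are in per-recording normalised units; absolute published
  DTW magnitudes are not reproduced (raw study data were not
  deposited), only orderings, trends, and the printed worked
  arithmetic.
* Whether published headline DTW values derive from accelerometer SVM,
  gyroscope SVM, or both is not stated; the pipeline defaults to
  accelerometer and can score the gyroscope stream in parallel
  (`sources` config).
* The relationship between a material's overall "DTW mean" and the mean
  of its six per-bin values is not specified in the source material
  (the published overall means exceed the bin means); the package
  emits both statistics and forces no relationship between them.
* No post-hoc tests, no mixed/repeated-measures models, no multivariate
  DTW, no FastDTW approximation, no barycenter averaging.
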