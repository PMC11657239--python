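# gaitwalk

Quantitative walkability assessment of sidewalk flooring materials from
wearable IMU gait recordings.

How walkable a surface is — how stably and comfortably people walk on it,
and how quickly walking on it fatigues them — is usually judged
subjectively. `gaitwalk` implements a sensor-based alternative: a single
lumbar-mounted inertial measurement unit (IMU) records tri-axial
acceleration and angular velocity while a participant walks a fixed
course, and the stability of their gait is quantified by how much each
gait cycle deviates from a reference cycle under Dynamic Time Warping
(DTW). Aggregating those deviations by flooring material, cumulative
walking distance, and age group turns raw accelerometry into comparable
walkability numbers: low, stable DTW means a stable walking surface;
DTW rising across distance is the signature of accumulating fatigue.

## Method

For each recording the pipeline:

1. **SVM conversion** — collapses each tri-axial sample to its signal
   vector magnitude, `SVM = √(ax² + ay² + az²)` (same formula for the
   gyroscope axes), an orientation-robust scalar of movement intensity.
2. **Filtering and normalisation** — removes high-frequency noise with a
   zero-phase 4th-order Butterworth low-pass (6 Hz default; gait energy
   lies below that) and z-scores the series per recording.
3. **Gait-cycle segmentation** — splits the series at successive
   prominent SVM peaks (one peak per foot impact) into cycles, dropping
   implausible durations (outside 0.4–2.5 s by default).
4. **DTW scoring** — each cycle `x` is scored against the stratum's
   reference cycle `r` by
   `DTW(x, r) = min_π Σ_(i,j)∈π |x_i − r_j|`, the minimum summed local
   cost over all monotone, continuous, boundary-respecting warping paths
   π. The reference ("typical") cycle of each (material, age-group)
   stratum is the DTW **medoid** — the observed cycle minimising its
   summed DTW distance to the others.
5. **Aggregation and statistics** — per-cycle scores are aggregated into
   mean/SD/range cells per material × age group × 200 m distance bin
   (six sections of a 1,200 m walk), per-participant means, percent-change
   tables, one-way ANOVA of SVM intensity across materials, and Tukey
   boxplot / histogram summaries.

Because no public gait recordings accompany the study design, the
package includes a seeded synthetic cohort generator
(`gaitwalk.synthetic`) that emulates it: 80 participants across five age
groups (20–30 … 60+), each walking 1,200 m on wood, asphalt, concrete
block, and cement, with per-material SVM distributions matched to the
published means/SDs and cycle-shape jitter that grows with distance
(fatigue) at an age- and material-dependent rate.

## Worked example

Run the full pipeline on a small simulated cohort (2 participants per
age group, runtime-scaled walks):

```bash
cat > config.yaml <<'YAML'
seed: 42
sources: [accel]
simulate: {n_per_group: 2, walk_scale: 0.1}
max_reference_candidates: 20
YAML
gaitwalk run --config config.yaml --out results
```

`results/percent_change.csv` then contains (abridged):

```
source,material,comparison,baseline,value,percent_change
accel,cement,first_to_last_bin,3.1995,3.4660,8.3
accel,wood,first_to_last_bin,1.6209,1.8513,14.2
accel,cement,youngest_to_oldest,3.1654,3.4622,9.4
accel,wood,youngest_to_oldest,1.6461,1.8010,9.4
```

Reading: on this simulated cohort the mean DTW deviation on cement rises
8.3% between the first and last 200 m section (fatigue accumulating over
the walk), and cement's absolute level (≈3.2, in normalised SVM units)
is roughly double wood's (≈1.6) — harder surfaces destabilise gait more.
`results/anova.csv` reports the one-way ANOVA of mean SVM intensity
across the four materials (here F = 23.1, p = 1.6e-08: material changes
movement intensity significantly), and `results/cohort_summary.csv`
holds the full material × age × distance-bin cell table. Every output
names the config hash and seed in its header, and identical config +
seed reproduces byte-identical tables.

The same stages are available as `simulate`, `preprocess`, `segment`,
`score`, and `report` subcommands, and as library functions
(`gaitwalk.dtw_align`, `gaitwalk.select_reference`,
`gaitwalk.analyze_cohort`, …).

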