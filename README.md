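# facecoord

Facial-behavior coordination analysis: from per-frame 3D face fits to a
diagnosis classifier and its comparison against human rater panels.

The pipeline:

1. **mesh_regions** — partition a dense face mesh into four regions
   (brows/forehead, eyes, nose/cheeks, mouth/chin) by nearest-landmark
   assignment, localize a global expression basis to those regions
   (60 components by default), and project per-frame deformations onto it.
2. **behavior_series** — convert rotation matrices to yaw/pitch/roll and
   stack 53 retained expression channels with 3 pose channels into a
   56 × T behavior matrix.
3. **coordination_features** — windowed forward-lag cross-correlation:
   for every ordered channel pair, the mean and standard deviation across
   50%-overlapping windows of the per-window maximal Pearson correlation
   over forward lags (6272 features for 56 channels).
4. **diagnosis_classifier** — linear SVM (C = 1) under repeated nested
   cross-validation where the only tuned hyper-parameter is the window
   length Tw ∈ {1, 2, 4, 6} s; leave-one-out and repeated k-fold
   per-participant accuracy; confusion-matrix metrics; fold-level weights.
5. **rater_comparison** — rater-panel accuracy by expertise stratum,
   per-participant human accuracy, hard-case extraction, and the
   human-vs-model agreement correlation with a near-unanimous exclusion
   rule.
6. **feature_importance** — category-level weight summaries: per
   region-pair |weight| statistics and top-k category-share curves under
   two counting conventions (slot / membership).
7. **synthetic_data** — everything needed to exercise the pipeline without
   real recordings: face-mesh fixtures, AR(1) cohorts with group-dependent
   lagged channel coupling, and rater panels from a logistic
   skill/difficulty model. Fully seeded and reproducible piecewise.

## CLI

```sh
# write a synthetic cohort (series files, labels, rater panel, ground truth)
facecoord simulate --out data/sim --seed 1

# per-Tw coordination feature tables
facecoord extract --series-dir data/sim --labels data/sim/labels.csv \
    --out data/features --tw 1 --tw 2 --tw 4 --tw 6

# nested-CV classification report + fold-averaged weight table
facecoord classify --features-dir data/features --labels data/sim/labels.csv \
    --out data/report.json --weights-out data/weights.csv --repeats 10

# category-level importance summaries
facecoord importance --weights data/weights.csv --out data/importance

# human-rater vs model comparison
facecoord compare --panel data/sim/panel.csv --labels data/sim/labels.csv \
    --ai-report data/report.json --out data/comparison.json

# convert a raw per-frame fit file (9 rotation entries + 60 coefficients)
facecoord convert --raw raw.csv --basis basis.csv --regions regions.csv \
    --out series.csv
```

## Conventions

- Channel order is fixed: 53 expression channels (region-major:
  brows/forehead, eyes, mouth/chin) followed by `pose_yaw`, `pose_pitch`,
  `pose_roll`.
- Euler angles are intrinsic Z-Y-X (yaw, then pitch, then roll), degrees.
- Feature names are `mu(chA->chB)` / `sigma(chA->chB)`; `(i, j)` means
  channel i leading channel j (forward lag applies to the second channel).
- All indices are 0-based; all on-disk formats are delimited text.
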