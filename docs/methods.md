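# Methods

`endoeval` implements a simulator-independent evaluation pipeline for
endoscopic (laparoscopic box-trainer style) skill training, in which each
exercise attempt is summarised by a multimodal feature vector and the
feature set is analysed for (i) time-dependent learning effects, (ii)
2D-vs-3D endoscope-mode differences and (iii) its ability to predict the
endoscope mode. Because the original study recordings are not publicly
available, the package ships a seeded synthetic-cohort generator that
emulates the study's measurement setup and injects known, configurable
effects; all statistical claims the test suite makes are therefore
parameter-recovery and calibration claims about the pipeline, not about
real surgical data.

## Study structure emulated by the generator

Fifteen volunteers, split 7 (2D endoscope) vs 8 (3D stereoscopic), each
perform 3 exercises with 9 attempts, recorded continuously in files of 3
attempts. Every attempt is opened and closed by a synchronisation gesture —
a raise of the main (right) hand and arm — and is aborted at 90 s. Three
participants are excluded (emulating data corruption), leaving
12 × 3 × 9 = 324 attempt datasets. The generator produces 15 × 27 = 405
attempt datasets before exclusion.

Streams per recording file:

* **sEMG**, 8 channels at 200 Hz (armband-typical), in arbitrary 8-bit-like
  amplitude units. The model is band-limited coloured noise (4th-order
  Butterworth band-pass, 20–95 Hz) modulated by a burst envelope during
  attempts (quiet floor ×0.12 between attempts), plus sparse biphasic
  motor-unit-like transients (0.25/s per channel, amplitude 60–85 a.u.)
  that dominate the signal extrema. This separation of a modest-variance
  carrier (active SD ≈ 5 a.u.) from large, rare transients reproduces the
  empirical ordering of raw feature scales in which the extrema metrics
  (V_Max, V_Min, V_Range) sit far above the variance, as they do for spiky
  surface EMG digitised by an 8-bit armband. The 2D group's sEMG is
  multiplied by `effect_amplitude` (default 1.5).
* **Orientation** (roll/pitch/yaw, rad) at 50 Hz: smoothed wander
  (≈0.3 rad) during attempts with a small sensor-noise floor.
* **Skeleton**: 8 upper-body parts (head, shoulder centre, left/right
  elbow, wrist, hand) × 3 coordinates at 30 Hz. Each part performs a
  smoothed random walk around a resting anchor with a weak mean-reverting
  pull; each attempt's realised mean speed is pinned exactly to its target
  so that the per-attempt speed trend is the dominant between-attempt
  structure. Right hand/wrist target speed declines by `effect_trend`
  (default 5%) per attempt with 2% log-normal attempt-to-attempt
  variability — a mean-velocity summary over a ~45 s tracked attempt is in
  reality very stable, and the variability must sit below the trend step
  for the trend to be identifiable at session scale. Position jitter is
  0.5 mm per frame; larger jitter adds spurious path length comparable to
  the true hand motion and masks kinematic structure.

Attempt durations are log-normal (mode 45 s, log-SD 0.35), hard-capped at
90 s with an abort flag (≈5% of attempts). Sample rates are fixed at
armband/depth-camera-typical values; the protocol itself never specifies
them.

All randomness flows from a single integer seed through spawned
`numpy.random.SeedSequence` children (one per participant, one per file),
so any sub-cohort is bit-reproducible and, in particular, exercise 1 is
identical whether or not the other exercises are simulated.

### What the generator does not emulate

Real recordings would contain device dropouts, clock desynchronisation
between sensors, non-stationary fatigue-related spectral shifts,
task-phase-locked motion patterns and genuinely heterogeneous participant
skill. Passing tests therefore demonstrate that the pipeline recovers the
effects it is told exist under clean, exchangeable noise — not that the
pipeline would reach comparable accuracies on real cohorts.

## Segmentation

The right hand's vertical (Y) track is compared against a centred running
median (10 s window); contiguous excursions ≥ 0.25 m lasting ≥ 1 s are sync
gestures. Gestures are paired (1,2), (3,4), … and each attempt is the data
strictly between a pair, on every stream's native clock (no resampling).
A `boundary_guard_s` margin (default 0.25 s) is trimmed beyond the detected
raise extents: thresholded detection only sees the raise above the height
threshold, and without the guard the sub-threshold ramp portions (the hand
descending/ascending ~0.25 m at each edge) leak ≈0.5 m of gesture motion
into each attempt's kinematics. A manual boundary file (per-recording
(t_start, t_end) pairs) overrides detection, mirroring the original manual
marking protocol. Attempts spanning ≥ 89.5 s are flagged aborted.

## Per-attempt features (160 canonical metrics)

13 sEMG features per channel (104 columns) and 7 motion analysis
parameters (MAPs) per body part (56 columns):

* Spectral: `f_Max`, `f_Min` (most/least powerful frequency of the
  mean-removed boxcar periodogram restricted to 10–95 Hz; ties break to the
  lowest frequency), `f_Range = f_Max − f_Min` (kept signed; an
  absolute-value switch exists), `P_Max`, `P_Min`. The band excludes DC and
  motion drift below 10 Hz and the Nyquist edge at 100 Hz. In density
  scaling the full-band integral of the periodogram equals the signal
  variance exactly (Parseval), which the tests verify.
* Amplitude: `V_Max`, `V_Min`, `V_Range`, `V_RMS`, `V_Var` (population
  variance, divisor N).
* Morphology: `V_SSC` (strict sign changes of consecutive first
  differences), `V_ZC` (strictly sign-changing sample pairs; zeros do not
  count), `V_WFL` (sum of absolute sample-to-sample changes).
* MAPs per part: `Trace` (path length), `Velocity = Trace/duration`,
  `POC` (vertical direction reversals debounced with 2 cm hysteresis),
  and `Angle_Mean/Max/Min/Range` of the angle between the per-frame body
  axis (shoulder centre → head, falling back to global vertical when
  degenerate) and the part's limb-segment vector (hand→wrist, wrist→elbow,
  elbow→shoulder centre, head→shoulder centre and its reverse for the
  shoulder centre itself — the protocol leaves the "normal vector of a
  body part" undefined, so the limb segment is used).

Extensive metrics that grow with attempt length — `V_SSC`, `V_ZC`, `V_WFL`
and the orientation AUCs — are divided by the attempt's sample count by
default (configurable), keeping attempts of different durations comparable.

Four orientation metrics (Roll/Pitch/Yaw AUC — trapezoidal integral of the
absolute trace over sample index — and `FES`, the mean-over-channels
`f_Max` divided by the mean of the three AUCs) are computed as well, but no
per-channel/per-part multiplication fits them inside a 160-column layout
(13×8 + 4 + 7×8 = 164); they are therefore carried as optional extra
columns outside the canonical 160 and outside every count that cites 160.

Missing entries (degenerate streams) are mean-imputed within
exercise × endoscope group before analysis, preserving group means. For
classification each column is min-max normalised to [0, 1] over all
attempts of the exercise; constant columns map to 0.5.

## Repeated-measures ANOVA (sessions of three attempts)

For each feature and each session (attempts 1–3, 4–6, 7–9) a split-plot
model is fitted with the attempt index (k = 3) as the within-subject
factor, participants as the random factor and endoscope mode (g = 2) as the
between factor. Sums of squares use the classical within-subject
decomposition via effect coding (Type III; exact for balanced groups,
well-defined for the 7-vs-8 split): SS_time (df 2), SS_time×endoscope
(df 2), SS_error (df 2(N−g)). Sphericity violation is corrected by
Huynh–Feldt epsilon: the Greenhouse–Geisser estimate
ε_GG = tr(M)²/((k−1)tr(M²)) with M = C S Cᵀ (C orthonormal contrasts,
S the pooled within-group covariance, divisor N−g), adjusted to
ε̃ = (N(k−1)ε_GG − 2)/((k−1)(N − g − (k−1)ε_GG)) and clipped at 1; both
F-test degrees of freedom are multiplied by ε̃ (for the time and the
interaction test alike). Degenerate (constant) data yields ε̃ = 1 and
p = 1. Balanced-design F statistics agree with an independent mixed-ANOVA
implementation to 10 decimals in the tests, ε_GG with the eigenvalue
formula to 1e-10, and the empirical time-effect type-I error under the
exchangeable null is 3.9% over 1,000 replicates.

p-value sets are summarised as −log10 boxplots per session and effect with
the 1.5·IQR whisker convention and significance ticks at 1.3010, 2 and 3
(p = 0.05, 0.01, 0.001). No multiple-testing correction is applied by
default (matching the emulated analysis); a Benjamini–Hochberg flag exists.

## Distance maps

Per exercise, each metric's attempts form one vector per endoscope group.
For every ordered pair (2D metric i, 3D metric j) all |v2D|×|v3D| scalar
distances are enumerated, sorted, and the median (midpoint convention for
even counts) stored — 160 × 160 = 25,600 cells per exercise and algorithm.
Euclidean cells use |a−b|; Mahalanobis cells divide by the square root of
the pooled variance of the two vectors' concatenated values (the scalar
covariance "between two vectors" of unequal length is otherwise
ill-defined; this choice is symmetric in the groups and degenerates to the
textbook scalar Mahalanobis distance — a row-metric-only variance mode is
configurable). Distances are computed on raw feature values by default
(normalisation enters only at classification); a normalised-input mode
exists. Cells with zero pooled variance are flagged missing.

The reduced map averages cells by affiliation — 13 sEMG feature groups
(over 8 channels) and 8 body-part groups (over 7 MAPs), plus 4 orientation
singletons when the optional columns are included — and both maps order
rows/columns by descending mean. On raw values the cross-metric cells are
scale-driven, so no diagonal dominance is assumed; instead the maps are
invariant to attempt permutation within groups, and the Euclidean map of
pre-standardised vectors equals the Mahalanobis map (tested).

## Feature selection and classification

A metric is retained iff any cell of its row in the full map reaches 85% of
the map's maximum cell ("upper 15% of the distance values"); an empty
selection falls back to all features with a warning.

The 18-learner roster mirrors a standard interactive toolbox: SVMs
(linear; quadratic/cubic polynomial with coef0 = 1; Gaussian with kernel
scale √P/4, √P, 4√P for P features, i.e. γ = 1/(2s²)), KNNs (k = 1, 10,
100; cosine and Minkowski-p3 metrics; distance weighting), a decision
tree, a 30-tree random forest ("bagged trees"), AdaBoost over depth-3
trees ("boosted trees"), random-subspace ensembles (half the features per
member) over LDA and over 1-NN, and an RUS-boosted variant implemented as
seeded random undersampling of the majority class followed by AdaBoost
(no imbalanced-learning dependency is used). Hyperparameters are
config-overridable; no search is performed.

Evaluation is stratified 5-fold cross-validated accuracy (%) predicting
the endoscope mode on the normalised table, with fold assignments fixed by
seed and shared across learners. Folds split by attempt by default,
matching the row-wise protocol being emulated; note that attempt-wise
folds place attempts of one participant in both train and test, so a
classifier can sit above chance on a null cohort by recognising
participants rather than the endoscope mode. The participant-grouped mode
(`group_by_participant=True`) measures true across-participant
generalisation and is what the null-calibration test uses; the headline
strong-effect accuracies are far above either baseline.

## Numerical and procedural choices

* Periodogram: plain boxcar, mean removal only; ≥ 64 samples required,
  shorter channels yield missing features and a warning.
* Tie-breaks: spectral argmax/argmin to the lowest frequency; zeros do not
  count as zero-crossings; POC's initial direction is established, not
  counted.
* Abort flag threshold 89.5 s guards against sampling offsets around the
  90 s cap; stored durations clip at 90 s.
* Scales chosen for the problem sizes the checks run at: calibration and
  recovery suites use single-exercise cohorts (identical, by seeding, to
  exercise 1 of the full cohort) with 20 fixed replicate seeds; the
  RANOVA type-I simulation uses 1,000 direct draws of 12×3 session
  matrices. The structural check runs the full 15-participant,
  3-exercise cohort once.

## Known limitations

* The Mahalanobis variant is scalar by construction; it does not model
  covariance between different metrics.
* The 160-metric layout is one documented resolution of an ambiguous
  count (the four orientation metrics cannot be inside it); downstream
  counts would shift by 4 under the alternative reading.
* RUS-boosting undersamples once per fit rather than per boosting round.
* Attempt-wise CV overstates generalisation for correlated attempts; use
  the grouped mode for participant-level claims.
* The generator's exchangeable noise cannot expose pipeline weaknesses
  that only non-stationary or artefact-laden real data would trigger.
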