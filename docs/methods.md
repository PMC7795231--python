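# Methods

## Problem and model

The package recognises five gross sleep postures — Stand, Supine,
RightLateral, LeftLateral, Prone — from wearable tri-axial accelerometers.
The core assumption is static-posture gravimetry: when the body is at
rest, each sensor's low-pass signal is dominated by the gravity vector in
the sensor frame, so posture is a direction-classification problem. A
chest sensor, strapped flat against the sternum, has a fixed (up to an
unknown in-plane mounting angle) relationship to the trunk and can be
labeled by deterministic rules; a wrist sensor's relationship to posture
is statistical — people place the arm differently — and is learned.

### Chest labeling

Calibration estimates only the in-plane mounting angle
`θ = atan2(mean_y, mean_x)` from an upright reference interval (default
first 5 s of the session; the duration is configurable and any upright
stretch works). The rotation is strictly planar — Z is untouched — because
a button-shaped sensor taped flat to the chest can rotate only about its
own Z axis. The reference statistic is the arithmetic mean of the interval,
consistent with the windowed averaging used everywhere else. Degenerate
references (zero X–Y mean, i.e. the sensor lying flat) raise an error
rather than guessing.

Noise removal targets one artifact: spurious near-zero samples. Within
each 1 s window the population variance `v` of the sample vector
magnitudes is computed and used as a threshold; samples with magnitude
`< v` are dropped. On steady data `v ≈ noise variance ≪ 1 G`, so real
samples are never dropped; a glitch inflates its own window's variance far
above its own magnitude and is removed. The comparison statistic is
magnitude (axis-symmetric); a per-axis variant is available behind a
config switch. A window of identical samples has `v = 0` and is never
touched.

The dominant-axis rule classifies each window by `argmax |mean|` over
(X′, Y′, Z) with sign disambiguation for the lying postures. Exact
dominance ties have measure zero on real signals; they are broken by the
fixed priority X′ > Y′ > Z and logged. Windows are half-open
`[k·w, (k+1)·w)`, 1-based in index; a record at exactly `t = w` belongs to
window 2. The last partial window is kept if non-empty.

### Wrist features and dataset assembly

Frames use the same half-open 1000 ms convention, and each frame is
reduced to its per-axis means — deliberately minimal features; variance,
frequency-domain or orientation-angle features are out of scope. Wrist
frames and chest labels are joined on the window index over the shared
session clock (both sensors stream to the same collector); clock-skew
correction is out of scope. Unmatched rows on either side are dropped and
counted. Stand windows are retained as a fifth class by default (the label
set includes Stand); a flag trains sleep-only models.

## Classifiers

**One-against-all SVM.** One soft-margin binary RBF SVM per class on
±1-relabeled data. The dual

    max_λ Σλ_i − ½ Σ_ij λ_i λ_j ŷ_i ŷ_j K(x_i, x_j),  Σλ_i ŷ_i = 0,  0 ≤ λ_i ≤ C

is solved by libsvm's SMO (through scikit-learn) with tolerance 1e−8; the
stored dual solution (support vectors, λ_i·ŷ_i, bias) is evaluated
natively at prediction time as `sign(Σ λ_i ŷ_i K(x_i, z) + b)` with the
convention `sign(0) = +1` (a measure-zero event that needs a deterministic
answer). Voting is literal: a "+" outcome adds one vote to the model's own
class, a "−" outcome adds one vote to *every other* class; the argmax of
the tally wins and ties go to the earliest class in the fixed order
Stand < Supine < RightLateral < LeftLateral < Prone, with a warning. A
consequence worth knowing: if every binary model answers "−" (an ambiguous
point), all classes tie and the fixed order elects Stand. A margin-argmax
alternative is available behind `use_margin=True`. Defaults `C = 1` and
`γ = 1/(n_features · var(X))` are conventions, exposed in the API; no
principled values exist for this feature scale, and the separable profile
is insensitive to them over orders of magnitude.

**Random forest.** Bootstrap-resampled Gini trees with `sqrt` random
feature subsets (scikit-learn trees), seeded. Prediction is a strict
per-tree majority vote with the same fixed-order tie-break — not
probability averaging — so a one-tree forest is exactly its tree. The
tree count is selected by one seeded random 2/3–1/3 split, training
forests with 1..50 trees and keeping the best validation accuracy,
smallest count on ties. A random split can leave a rare class (typically
Stand, which only covers the calibration prefix) out of the validation
side; `select_tree_count` treats that as an error per its contract, and
the end-to-end pipeline retries with derived seeds. The smallest-on-ties
rule means perfectly separable data select very small forests (often 1–7
trees), which is faithful to the protocol but worth remembering when
reading repeated-trial accuracies.

## Evaluation protocols

A "trial" is one windowed feature vector. Overall accuracy is
trace/total of the 5×5 confusion matrix. The repeated-trial protocol
re-splits (2/3–1/3), re-trains and re-tests `n` times with per-trial seeds
`base_seed + t`, so longer runs extend shorter ones; class-incomplete
splits are redrawn (counted, capped at 20 attempts). Summaries report
mean, 25th/75th percentiles, and outliers beyond 1.5·IQR (Tukey's rule —
the conventional box-plot definition). Cross-subject transfer trains on
one dataset and tests on another. The multi-session summary reports the
mean accuracy and the count of sessions *strictly* above a threshold
(default 0.82).

## Synthetic sessions

The simulator emulates exactly what the pipeline consumes, no more:

* **Chest**: canonical gravity per posture — Stand (1,0,0),
  LeftLateral (0,1,0), RightLateral (0,−1,0), Supine (0,0,1),
  Prone (0,0,−1) in the calibrated frame — rotated by a per-session
  mounting angle (default drawn uniform on (−π, π]) that calibration must
  undo.
* **Wrist**: posture-conditioned unit orientations, by default pairwise
  ≥ 90° apart. The orientation is re-drawn around its posture mean with
  angular dispersion `wrist_orientation_sd` once per second. The 1 s
  granularity is a deliberate choice: with a truly static per-posture
  orientation, a frame-level random split puts frames of every dwell
  segment on both sides, the classifier memorises each segment's exact
  orientation, and no amount of between-segment dispersion produces
  held-out confusion. Re-drawing at the frame timescale models a wearer
  who keeps adjusting the arm, and makes each held-out frame a genuinely
  unseen placement draw.
* **Noise and artifacts**: i.i.d. Gaussian per-axis sensor noise
  (default sd 0.05 G — small against the 1 G signal but large enough that
  cleaning and averaging matter); glitch samples (direction random,
  magnitude < 0.01 G) injected at `glitch_rate` from an RNG stream
  independent of the noise stream, so a session and its glitch-free twin
  differ only at glitched samples; clipping to the ±2 G range, logged.
* **Truth**: every complete 1 s window is labeled with the posture
  occupying the majority of its duration.

Every session begins with a 5 s Stand segment so calibration is always
possible. Two profiles are provided. `separable` (the default study
condition): orthogonal wrist means, dispersion 0.1 rad, no overlap,
balanced dwells — two visits of 15 s to each lying posture (125 windows
per session, ~7.5k samples per stream; sized so the full suite and the
acceptance script run in seconds while every class has dozens of
windows). `confusable`: the prone wrist mean is mixed 0.6 of the way
toward the right-lateral one (≈ 34° apart after renormalisation),
dispersion 0.35 rad, and right-lateral dwells doubled — so prone/right-
lateral placements genuinely overlap and the boundary is biased toward
the better-represented right-lateral class, making prone the
hardest posture to recognise from the wrist.

What passing tests on these sessions do **not** show about real data: real
wrist dynamics (movement, drift, non-Gaussian artifacts), attachment slip,
between-subject anatomy differences, or realistic posture schedules.
The simulator establishes correctness of the machinery and qualitative
phenomena (e.g. prone confusion under wrist-placement overlap), not
field accuracy.

## Numerical choices

* Timestamps are integer milliseconds; float inputs are truncated with a
  warning. Sampling at 60 Hz uses rounded timestamps (`round(k·1000/60)`),
  which stay strictly increasing.
* Calibration angle is folded into (−π, π]; `atan2`'s −π endpoint maps
  to +π.
* SVM solver tolerance 1e−8 (so dual feasibility holds to ≤ 1e−6);
  iteration cap 10⁶ with a diagnostic error on non-convergence.
* All randomness flows through `numpy` `SeedSequence` spawning; identical
  configs give bit-identical sessions, and model training is reproducible
  per seed. Model archives (joblib, versioned) reload to bit-identical
  predictions.
* Degenerate inputs raise typed errors early: empty streams, non-monotone
  timestamps, single-class training data, class-incomplete validation
  splits, empty post-cleaning streams.

## Known limitations

* The raw line dialect is specified loosely upstream; the parser fixes
  `{timestamp,ax}{ay,az}` (X with the timestamp) and would need a dialect
  table entry, not a change, if files in the wild differ.
* The literal OAA voting rule sends all-negative points to the first
  class in the fixed order; use the margin option when that bias matters.
* Noise removal assumes the only artifact is near-zero glitches; it will
  not remove saturated or wildly-oriented samples.
* Calibration assumes a truly upright reference; a tilted reference
  biases θ and with it every lateral/stand decision.
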