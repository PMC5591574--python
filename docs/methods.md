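# Methods

`eyescript` reconstructs two-dimensional *eye-writing* traces from
four-channel periocular electrooculography (EOG) and classifies them as one
of ten digit patterns.  This note records the model assumptions, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not establish.

## Signal model

EOG voltage varies approximately linearly with gaze angle over moderate
ranges (the corneo-retinal standing potential acts as a rotating dipole).
With electrodes left/right of the eyes and above/below the right eye, the
bipolar derivations

    h = right − left,      v = above − below

track horizontal and vertical gaze.  A saccade appears as a step in `h`/`v`;
fixation segments are near-constant and carry no shape information.  The
observed vertical component additionally contains a fraction of the
horizontal one,

    v_obs = v_true + α·h,

because the above/below electrode pair is never placed perfectly
symmetrically about the horizontal axis of eye rotation.  Removing `α·h` is
the *crosstalk* (interdependency) compensation.

## Reconstruction pipeline

Stage order (each stage is exposed individually; `reconstruct` runs them
all):

1. **Downsample** to 64 Hz by polyphase anti-aliased decimation
   (line-extension padding — zero padding would fabricate step transients at
   the epoch edges of a signal riding on a large baseline offset).
2. **Median filter**, default 31 ms window (3 samples at 64 Hz): removes
   impulsive noise without blunting saccade steps.
3. **Blink detection** on the vertical bipolar channel.  The emphasis
   filter is a bank of paired moving-average differences (a smoothed first
   derivative) at 100/150/200 ms scales; the scale with the largest response
   wins and its window is the filter width `W`.  A blink — a large
   (~300 µV), ~300 ms bump — produces a local maximum followed within about
   its half-duration by a local minimum; the detected artifact interval is
   `[T(max) − W, T(min) + W]`.  An isolated saccadic step produces a single
   one-signed lobe and is never paired, and a rise–fall *pair* of strokes is
   separated by a fixation longer than the 250 ms pairing window, so strokes
   do not alias into blinks.  The amplitude threshold is `6 × MAD` of the
   filtered series, floored at 30 µV (a nearly clean record must not
   collapse the threshold onto numerical ripple) and capped at half the
   largest response (a short epoch dense with blinks must not inflate the
   MAD past the blinks themselves).
4. **Baseline removal** per channel: subtract the median of the 100 ms
   preceding the writing epoch (the first 100 ms of the record when no
   marker exists).
5. **Bipolar derivation** as above.
6. **Blink-gap interpolation**: samples inside each artifact interval are
   replaced by the straight line joining the neighbouring clean samples;
   intervals touching a record boundary hold the nearest valid value.
7. **Drift removal**: subtract the ordinary-least-squares line fitted over
   the full epoch, separately for `h` and `v`.  *Known consequence*: the
   writing staircase itself contributes to the fitted line, so digits whose
   gaze path trends monotonically (e.g. the descending strokes of 2, 3, 5,
   and both axes of 4) acquire a bounded shear — measured as up to ~0.25
   mean unit-box distance for the worst shape on noiseless data — while
   closed balanced shapes (0, 8) reconstruct to within 0.05.  Classification
   is robust to this systematic, shared distortion; it is kept because a
   single epoch-wide linear fit is the stated procedure.
8. **Saccade detection**: continuous wavelet transform with a Haar wavelet
   at scale 20 samples.  The coefficient at position `b` is the normalised
   half-window sum difference, so a step of amplitude `A` yields a peak
   `|C| = A·√a/2 ≈ 2.24·A`.  Samples with `|C| > θ` on either channel are
   saccadic; runs separated by under 2 samples merge and runs shorter than
   2 samples are discarded.  Default `θ = 120` (µV scale), overridable;
   `derive_threshold` reproduces the calibration procedure: per annotated
   saccadic region take the peak `|C|`, then the minimum across regions —
   the largest threshold that still detects every calibration saccade.
9. **Trace extraction**: the `(h, v)` pairs inside saccadic segments,
   concatenated in time order.
10. **Equidistant resampling** to 128 points at uniform arc-length
    positions.  All gaps between neighbours on a common straight span are
    identical chords; a gap straddling a corner is slightly shorter (the
    chord cuts the corner, bounded by one gap per corner).  An exact
    equal-chord placement with a fixed point count does not exist in
    general: the chord-walk residual jumps discontinuously whenever a chord
    starts to shortcut a corner, so uniform arc length is the well-posed
    reading of "equal Euclidean distance between adjacent points".
11. **Unit-box normalization**: each axis independently mapped to [0, 1]
    (aspect ratio deliberately not preserved); a zero-extent axis is centred
    at 0.5.
12. **Crosstalk estimation and removal.**  In central-finite-difference
    space (`s′(t) = s(t+1) − s(t−1)`), `α` is the least-squares slope of
    `dy` on `dx` *through the origin* — the unique value for which the
    compensated increments `dy − α·dx` have zero regression slope.  No
    intercept: the difference cloud of a written character is centred at the
    origin by construction, and an intercept would let the shape's net
    start-to-end displacement masquerade as crosstalk.  Identifiability
    rests on the writing's vertical increments being uncorrelated with its
    horizontal ones; this holds for patterns built from axis-aligned strokes
    and fails by construction for shapes dominated by one oblique stroke
    (the flag of '1', the diagonal of '7'), whose estimates carry an
    intrinsic shape bias of ~0.4–0.5.  That bias is a property of the
    estimator, not of this implementation; in practice the resulting shear
    is shared by test and training epochs and the classifiers absorb it.
    Because estimation happens after per-axis normalization, the recovered
    coefficient equals the injected `α` scaled by the axis-extent ratio
    `s_x/s_y`; compensation is exact in normalized coordinates either way.
    The trace is renormalized afterwards.

## Digit templates

The ten patterns are waypoint polylines on a 3×3 integer lattice
(`src/eyescript/data/digit_templates.json`, origin bottom-left, +y up),
designed from axis-aligned corner-to-corner strokes wherever the digit's
shape allows.  '1' keeps a two-stroke "flag + descender" form with the
descender on the centre column: a bare vertical bar would have zero
horizontal extent and break per-axis normalization.  Template traces go
through the same resampling and normalization as reconstructed traces and
contain no fixation samples.

## Dissimilarities and classification

Both measures operate on trace *increments* (derivative form), making them
position-invariant, with the step set `{(1,m), (m,1) | 1 ≤ m ≤ M}`,
default `M = 8` (~6 % of the 128-point length).  2-D increments are compared
with the L1 norm (an L2 option exists); predecessor indices below the first
sample clamp to it and the origin cell costs zero.

- **DTW** compares fixed one-step increments and adds the minimum
  predecessor cost over the step set.
- **DPW** takes each candidate step's increments *relative to that step's
  predecessor* (`A(i) − A(i − C_A(c))` vs `B(j) − B(j − C_B(c))`) and
  minimises increment cost plus predecessor cost jointly over steps.  For a
  step-independent cell cost this recurrence is algebraically identical to
  DTW's `cost + min`, of which it is the natural generalisation; the joint
  minimisation is a proper shortest path.  Warping thus acts on the value
  axis as well as time: a stroke traversed at a different pace is
  consolidated into one multi-sample increment instead of paying a
  per-sample mismatch.  Note the two measures' raw magnitudes are not
  comparable — DPW's increments span whole warp steps, so its scale is
  structurally larger; its advantage shows in classification accuracy, not
  in smaller raw within-class values.

Nearest-template classification picks the minimum-dissimilarity template
(ties break to the lowest label).  The SVM combination divides the ten
dissimilarities by per-class normalization factors (mean within-class
dissimilarity on training data) and trains a linear-kernel, one-vs-one
multi-class SVM (`C = 1`) on the resulting 10-vectors.  Models serialise to
JSON; the SVM is refitted deterministically from the stored training
features on load, which round-trips the decision function exactly.

## Validation

Leave-one-subject-out (LOSO): each fold holds out all epochs of one
participant and refits normalization factors and SVM on the rest; templates
are never refitted.  Trace-to-template dissimilarities do not depend on the
fold and are computed once.  A `holdout_group` supports cohorts that are
tested but never trained on.  Metrics: overall accuracy (trace of the
confusion matrix over its total), per-participant accuracy, and per-digit
precision/recall/F1; zero-denominator cases report 0 with an explicit
`undefined` flag so tables stay rectangular.  `visual_angle` converts screen
geometry to the full subtended horizontal angle, `2·arctan(w/2d)`.

## Synthetic data

`simulate_epoch` emulates one eye-written digit at 2048 Hz: logistic-sigmoid
saccades (60 ms default) through the template waypoints, 250 ms
inter-stroke fixations, 700 ms lead/tail fixations, 80 µV of bipolar EOG
per grid unit split symmetrically onto the single-ended channels,
per-channel baseline offsets (±100 µV) and linear drift (±3 µV/s), Gaussian
noise (5 µV SD per channel), raised-cosine blink bumps (300 µV, 300 ms,
Poisson 0.5/epoch, 20 % opposite-signed counterpart below the eye), optional
injected crosstalk `α`, and per-epoch waypoint jitter (0.06 grid units).
Blinks are placed inside fixation periods only — blinking is suppressed
during saccades, and a writing task concentrates blinks in the pauses.
`simulate_cohort` draws subject-level parameters once per subject (gain
0.85–1.15×, `α` ∈ ±0.3, noise 4–6 µV, saccade duration 50–80 ms, fixation
240–320 ms) and all randomness descends from one seed through deterministic
stream splitting.

What this does *not* emulate: microsaccades and high-frequency oculomotor
ripple, EMG/mains contamination, electrode impedance drift and sweat
artifacts, oculomotor slowing beyond a longer saccade-duration setting, and
any behavioural errors (extra or missing strokes).  Passing the simulated
checks therefore demonstrates the correctness and internal consistency of
the algorithms under the stated signal model, not clinical performance on
human recordings.

## Default problem sizes

The simulated validation cohort is 18 subjects × 3 trials × 10 digits
(540 epochs), mirroring a healthy-cohort exercise protocol; event-recovery
checks use 100 epochs; parameter-recovery checks use 250 injected traces.
These sizes make the whole suite and the acceptance script complete in a
few minutes on one CPU while keeping Monte-Carlo noise on the reported
rates near or below a percentage point.

## Known limitations

- Epoch-wide linear detrending shears trend-heavy digits (see stage 7);
  a fixation-anchored or robust detrend would remove this at the cost of
  departing from the single-regression procedure.
- The crosstalk estimator is biased for oblique-stroke shapes (stage 12).
- Equal-gap resampling is exact only between corners (stage 10).
- The blink detector assumes blink amplitude comfortably above stroke
  amplitude (default simulator: 360 µV bipolar vs ≤ ~160 µV); heavy-lidded
  small blinks would need a lower amplitude floor.
- EDF/BDF reading requires the optional `mne` dependency and maps channels
  by name through a user-supplied layout.
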