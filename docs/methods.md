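# Methods

`wristhar` implements a complete analysis pipeline for recognizing daily
activities — sitting at a computer, standing still, walking, running,
cycling — from a single wrist-worn triaxial accelerometer, under the two
data regimes that matter in practice: *free-living* (self-reported labels,
natural device placement, interruptions and sensor dropouts) and
*controlled* (clean protocol recordings).  Because real cohort data of
this kind cannot be redistributed with the package, a synthetic cohort
generator reproduces the statistical structure the analysis depends on,
and every stage is exercised end-to-end on it.

## Label cleaning

Self-reported activity intervals overlap when participants mislabel times
or activities.  Activities in the vocabulary are mutually exclusive, so
an overlap is an error, and the contested time is excised rather than
adjudicated:

* **Partial overlap** `[a, b) ∩ [c, d) ≠ ∅, a < c < b < d`: the earlier
  interval becomes `[a, c)` and the later `[b, d)` — the overlap leaves
  both.
* **Full containment**: the enclosing interval is truncated at the nested
  interval's start; the nested interval is removed.
* **Identical spans, different labels**: both removed (the
  enclosing/nested rule is undefined; this is the conservative choice).

Intervals are half-open `[start, end)` so touching intervals never
overlap.  Chains of more than two mutually overlapping intervals are
resolved by repeatedly fixing the first overlapping pair in start order;
each fix strictly reduces overlap, so the sweep terminates, the result
has zero pairwise overlap, and the procedure is idempotent.  Every edit
is logged and the total discarded duration equals the labeled-time
deficit exactly.  Adjacent same-activity intervals are *not* merged after
correction; window segmentation treats them independently.

## Signal processing and windowing

Signals are scaled affinely to the accelerometer's dynamic range of
±2 g (values outside are clipped and counted).  Streams recorded above
32 Hz (the controlled protocol records at 50 Hz) are reduced by mean
aggregation over contiguous bins of width 1/32 s; empty bins propagate
as gaps.

The classifier input is a 3×384 matrix: 12 s of X/Y/Z at 32 Hz.  Windows
are cut with a 6-s stride on a grid that restarts at each cleaned label
interval's start; a window is kept only if it lies wholly inside one
interval with all 384 expected samples present (checked with a tolerance
of a quarter sample period).  No imputation: a window touching a sensor
gap is dropped.  A gapless interval of `T` seconds therefore yields
`⌊(T−12)/6⌋+1` windows — 1199 for 120 min, 99 for 10 min, 49 for 5 min —
and this closed form is tested against brute-force enumeration.

## Partitioning

Per subject and activity, the earliest windows totaling a fixed labeled
time budget (defaults: computer table 120 min; cycling, running, walking
10 min; standing still 5 min) form the **personalization set**; the next
2 min of labeled time are discarded as a leakage gap; the remainder is
the **hold-out set** used to evaluate every model for that subject.  An
activity is excluded for a subject when its labeled time is below
budget + gap + ½·budget (the minimum-test rule).  The gap is excluded
from both sides' accounting.

Independently, all windows are assigned to 8 chunks by absolute time with
boundaries shared across subjects (equal-duration bins of the pooled
window-start range by default; configurable).  **Cumulative datasets**
CDS(k) = chunks 1..k give nested, growing training pools.  The general
model for subject X at CDS(k) is trained on CDS(k) minus X's windows;
subjects with no windows in CDS(k) share one model trained on the full
CDS (tracked by a reuse key so it is trained once).  Personalization
fractions (20…100%) take the time-ordered prefix of ⌊fraction·n⌋ windows
per activity, so fraction sets nest.

## Classifier

A 7-layer 1D CNN: valid convolutions at stride 1 with kernel sizes
(16, 17, 17, 17, 17, 17, 17) and channels (32, 32, 64, 64, 64, 128, 128),
swish activations and spatial (whole-channel) dropout between them;
global average pooling; dense layers of 32 and 16 units with ReLU and
ordinary dropout; softmax over the activity vocabulary.  The receptive
field is 1 + Σ(kᵢ−1) = 112 samples = 3.5 s at 32 Hz, enough to span
several gait cycles of every target activity.  Kernel sizes, channel
widths and the pooling choice are this package's defaults (the smallest-
surprise stack meeting the depth, dense-width and receptive-field
constraints) and are configurable.

Regularization: Gaussian noise added to the input and, transiently, to
the weights of the first two convolutional layers during training forward
passes (stored parameters stay noise-free); spatial and dense dropout.

**Rotational augmentation** precedes the network during training: each
window is left-multiplied by a random proper rotation built by
Gram–Schmidt orthonormalization of `B = (1−s)·I + s·M`, `M` i.i.d.
standard normal; if the result is a reflection the last column is
negated, so `det R = +1` always.  The strength `s ∈ [0, 1]` interpolates
between the identity (`s = 0` returns the identity exactly) and a fully
random rotation; it emulates session-to-session variation in how the
wristband sits on the wrist.  At evaluation time augmentation, noise and
dropout are all disabled.

Training regimes:

| regime     | epochs | optimizer | lr    | decay       | dropout | noise | rotation | batch |
|------------|--------|-----------|-------|-------------|---------|-------|----------|-------|
| free-living| 105    | Adam      | 8e-4  | ×0.3 / 30 ep| 0.15    | 0.03  | 0.2      | 600   |
| controlled | 270    | Adam      | 5e-3  | ×0.3 / 50 ep| 0.075   | 0.015 | 0.1      | 600   |

The engine is pure numpy with hand-written backpropagation and explicit
`numpy.random.Generator` seeding, so training is exactly reproducible:
same seed and data give bit-identical parameters, and frozen layers are
bit-identical before and after any continued training.

## Personalization

Transfer learning: convolutional layers 1–3 and both dense layers are
frozen (the softmax head too, by default — only conv 4–7 are named
trainable; a flag flips the head for sensitivity analysis), and training
continues with SGD on the subject's personalization windows.  The
learning rate is increased (×2 the general base rate by default) and
regularization strengthened (noise and dropout ×1.5).  These multipliers
are deliberately modest: the personalization sets are tiny (tens of
windows), and stronger settings (×10 lr, ×2 noise/dropout) made the
continued training diverge — the personalization loss *rose* — on the
synthetic fixtures.  The increase-direction is the design intent; the
magnitudes are package defaults and fully configurable.

## Metrics

Balanced accuracy = mean per-class recall; F1-micro from globally pooled
TP/FP/FN (equal to plain accuracy for single-label multiclass output);
F1-macro = unweighted mean of per-class F1; F1-weighted = support-
weighted mean; logloss = −(1/N)ΣᵢΣⱼ yᵢⱼ log pᵢⱼ with probabilities
floored at 1e−15.  Classes with zero true support in a hold-out set are
excluded from BA/F1-macro/weighted averages and reported separately
(hold-out sets legitimately miss activities); `strict_zero_support=True`
restores the stricter count-as-zero convention.  All formulas are tested
to 1e−9 against scikit-learn on random inputs.

## Feature baseline

The supporting classifier band-passes X, Y, Z and the Euclidean norm EN
(Butterworth order 4, 0.3–12 Hz by default — removes gravity drift,
keeps locomotion harmonics), cuts 15-s windows with 50% overlap, and
emits exactly 42 features per window: per channel the mean, min, max,
standard deviation, kurtosis, skewness, RMS and interquartile range
(32); per channel the dominant frequency (DC excluded) and spectral
entropy (8); the spectral energy of EN and the summed X+Y+Z spectral
energy (2).  This inventory is the canonical, versioned list
(`wristhar.baseline.FEATURE_NAMES`).  Features are standardized with
statistics fit on training folds only.  The classifier is a LightGBM
gradient-boosted ensemble tuned by leave-one-subject-out CV over tree
count, learning rate, depth and L2 regularization, then refit on all
data.

## Synthetic cohorts

Each subject has a profile: cadences (walking ≈1.6–2.2 Hz, running
≈2.4–3.2 Hz, cycling ≈0.8–1.5 Hz), per-activity amplitudes, per-posture
gravity directions, a wrist-placement rotation (uniform axis, angle
uniform up to 45°), a labeling bias (probability that a short
interruption is absorbed into the surrounding self-report label), an
interruption rate and a noise level.  A bout's signal is gravity (the
posture unit vector, 1 g) plus, for locomotion, three harmonics at the
cadence with fixed relative amplitudes (1, 0.4, 0.15) in the plane
transverse to gravity, plus white noise; static activities get a slow
postural sway instead.  The subject's wrist rotation is applied last, so
un-rotating a stream recovers the same-seed identity-orientation
template exactly — the property the rotational augmentation layer
targets.

Free-living mode adds: interruptions (5–30 s of another activity inside
bouts, split in the ground truth, absorbed into the self report with the
labeling-bias probability), boundary jitter on self-reported bout edges,
overlapping labels injected by extending a bout's reported end past the
next bout's start with configured probability, occasional mislabels, and
sensor gaps (whole spans removed).  Controlled mode emits uninterrupted
exact-duration bouts (1 min per activity by default, four activities) at
50 Hz with identity orientation and zero label noise — a stand-in for a
filmed lab protocol.  Timestamps are exact 1/rate grids within bouts, so
window-count formulas are exact.

What the generator does **not** emulate: within-bout cadence drift and
pace variation, transitions between activities (signals switch
instantaneously), non-stationary noise, device-specific transfer
functions, and any physiological channel.  Passing tests therefore
demonstrate the pipeline's correctness and the direction of the studied
effects under the stated signal model, not field performance on real
recordings.

## Scaled-down studies and problem sizes

The shipped studies re-create the two headline experiment directions at
desk scale (narrow channels (8, 8, 8, 8, 8, 16, 16) — same depth,
kernels and receptive field — short schedules, capped training sets):

* **Personalization gain**: 10 seeded 5-subject cohorts (6 min per
  activity, 1.5-min budgets) whose target subject wears the device
  rotated ≈150° out of the population range; general model trained on
  the other four subjects (14 epochs, ≤400 windows), personalized 10
  epochs.  Mean hold-out balanced-accuracy gain is positive, echoing the
  finding that personalization helps most when the target deviates from
  the training population; with a matched target the gain is near zero.
* **Domain gap**: per seed, a model trained on a clean fixed-orientation
  controlled cohort and one trained on free-living data (15 epochs,
  ≤300 windows) are evaluated on the same free-living hold-out over the
  shared four-activity vocabulary; averaged over 10 seeds the
  controlled-trained model scores lower.

The demo grid (6 subjects, computer table 12 min / others 3 min budgets,
30-s gap, 2 chunks, fractions 20% and 100%) runs the full
general + personalization grid in minutes and reproduces its CSVs
bitwise across reruns with the same seed.

## Numerical choices and edge cases

* Gap tolerance in windowing and coverage accounting: a quarter sample
  period; a one-second coverage bin counts when it holds at least the
  expected samples minus one.
* Equal-span overlapping labels: both removed.  Zero-length leftovers of
  correction are dropped.
* Down-sampling bins are anchored at the stream's first timestamp; an
  epsilon (1e−9 s) guards bin-edge float jitter.
* He-style initialization; softmax probabilities clipped at 1e−15 in the
  loss; Adam with standard (0.9, 0.999) moments.
* Training with an empty class vocabulary entry is allowed: absent
  classes are recorded in provenance and the softmax still covers the
  configured vocabulary.
* All randomness flows through explicit seeded generators; grid model
  reuse keys are hashed with CRC32, not Python's randomized `hash`.

## Known limitations

The numpy engine is single-threaded-friendly but slow at the full
published schedules (105/270 epochs at batch 600 on hundreds of
thousands of windows); those regimes are retained as configuration
defaults for completeness, while the shipped studies use the scaled
schedules above.  The synthetic signal model makes the locomotion
classes close to rotation-invariant (cadence bands barely overlap), so
the domain gap and personalization effects are carried mostly by the
static postures; on real data orientation effects are broader.
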