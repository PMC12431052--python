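# Methods

`fallstream` re-creates, end to end, a fall-detection pipeline for commodity
wearables: a smartwatch on the left wrist and a smartphone on the right hip,
each contributing a 3-axis accelerometer and gyroscope sampled at a nominal
32 ms period. The pipeline covers synthetic data generation, sliding-window
sensor fusion, an encoder-only Transformer classifier trained on raw signals,
a streaming probability-averaging alarm trigger, user-feedback capture, and
feedback-driven retraining, evaluated with leave-one-subject-out (LOSO)
cross-validation over sensor combinations.

## The classification model

Each input is a window of 128 consecutive samples (~4.1 s at 32 ms), with one
row per time step holding the horizontally stacked 3-axis readings of the
selected channels (wA, wG, hA, hG — wrist/hip accelerometer/gyroscope), so a
wA+hA model sees 128×6 matrices. No filtering, normalization or handcrafted
features are applied: the model trains on raw gravity-inclusive signals.

The classifier is an encoder-only Transformer:

- linear projection of each row to d_model = 128, plus fixed sinusoidal
  positional encoding (chosen because it adds no learned parameters; the
  architecture description is silent on positional information);
- 4 encoder layers, each: 4-head self-attention
  `Attention(Q,K,V) = softmax(QKᵀ/√d_k)V`, heads concatenated and projected
  by `W_O`, followed by add & layer-norm (post-norm), then a position-wise
  FFN with hidden width d_model and add & layer-norm. Dropout 0.25 is applied
  to the embedding and to each sub-layer output during training;
- temporal mean-pooling over the 128 steps (the published description does
  not say how the sequence collapses to one logit; mean-pooling is the
  simplest order-agnostic choice);
- a prediction head Dense(8, ReLU) → Dense(16, linear) → Dense(1, sigmoid).
  The 8→16 head follows the source description literally: ReLU only between
  the two matrices, no activation after the second. The 8/16 dims are read
  as a single post-encoder head rather than per-layer FFN sizes, because
  residual addition inside encoder layers forces FFN output width = d_model,
  which 8/16 cannot satisfy. Both sizes are configurable.

Training minimizes binary cross-entropy with Adam (lr 1e-3, batch 32 —
unstated in the source; standard defaults, exposed in `TrainSpec`).
Experiments repeat 3 times with seeds `seed + r` and metrics are averaged.

The model is implemented directly in NumPy with hand-derived gradients
(no deep-learning framework is available in the target environment). The
backward pass is verified against central finite differences in the test
suite, and the attention forward pass against a literal double-loop
evaluation. The default configuration has exactly 400,425 parameters for a
6-channel input; this number is asserted in tests to guard architecture
drift. Float32 is used for training speed; float64 is available for
numerical verification.

## Windowing and fusion

Windows slide by `step_size` samples; the published description names the
parameter but not its value, so the default is 32 samples (~1 s, 75 %
overlap), the common HAR choice, which also makes the 10-prediction trigger
span ~13 s of context. All channels are linearly interpolated onto the
wrist-accelerometer clock (or the first present channel's clock) and
truncated to the common overlap, because watch/phone synchronization is not
described and stacking requires one row per time step. Windows inherit
their trial's label; impact-adjacent labelling is deliberately not
implemented (the source labels at trial level), which matters for
interpreting window-level metrics on long trials — see "Synthetic world"
below.

## Streaming trigger

Predictions start once 128 rows are buffered and continue every `step_size`
rows, reusing the buffer. An alarm fires when the mean of the last 10 raw
probabilities strictly exceeds 0.5; the average suppresses isolated positive
windows. After an alarm the probability history is cleared (default), so one
fall produces one alarm; a no-refractory policy is also implemented because
the deployed system's behaviour after an alarm is not described. Event-level
scoring matches triggers to annotated fall onsets within ±10 s (first match
wins); leftover triggers are FPs, unmatched falls FNs.

Feedback capture mirrors the deployed UI flow: a confirmed alarm stores the
triggering window as a TP event, a rejected alarm as FP; a user-reported
missed fall stores the window ending at the report plus the preceding window
as FN (the payload extent is unspecified in the source; two windows bracket
the fall and its aftermath); background TN windows are harvested on a fixed
cadence (default one per minute; the source's cadence is unstated) away
from triggers and falls.

## Feedback retraining

The retraining pool is base-cohort windows plus feedback: falls = base falls
∪ TP ∪ FN, ADLs = base ADLs ∪ FP ∪ a TN subsample (all, half, quarter, or
none, drawn uniformly without replacement; fractional sizes round half-up so
23,179/2 prints as 11,590). Retraining is always full training from scratch
with the same architecture — never fine-tuning — so the result is
independent of the previous model's weights. Overlapping feedback windows
are not deduplicated, matching the additive pool accounting of the published
tables.

## Synthetic world

The real recordings behind the original system are not publicly deposited,
so `fallstream.synthetic` generates a stand-in cohort with the documented
protocol (per subject: 5 fall types × reps, 8 ADLs × reps; 16 subjects × 5
reps gives 400 falls and 640 ADLs) and the documented signal morphology.
The signal model is gravity + parametric activity envelope + Gaussian noise
(0.3 m/s² per axis); per-subject amplitude/tempo factors (~N(1, 0.1))
model inter-subject variability; timestamps carry ±2 ms uniform jitter
(removable for exact tests).

- **Falls** (front/back/left/right/rotational): light pre-fall sway, a brief
  sub-gravity free-fall dip, one synchronized half-sine impact on both
  accelerometers with peak magnitude drawn in 15–20 m/s² (independently per
  site, rescaled so the noise-free peak hits the target exactly), a damped
  aftermath, and — crucially — a persistent post-impact posture change:
  gravity rotates 70–100° off the vertical while the subject lies on the
  mattress. The posture signature is standard fall phenomenology and is what
  makes most windows of a 12 s fall trial carry evidence despite trial-level
  labels; without it, windows that miss the ~2 s impact are label noise and
  window-level scores become uninterpretable.
- **Wrist-dominant ADLs** (wave, drink, jacket, wash_hands): oscillatory
  wrist bursts with peak magnitude also in 15–20 m/s² plus sustained wrist
  orientation plateaus (a rotated watch during washing/dressing), so the
  wrist channel alone is genuinely confusable with falls; the hip stays
  within noise of gravity (<2 m/s² deviation).
- **Whole-body ADLs** (walk, sit_stand, pick_up, sweep): moderate rhythmic
  motion at both sites, hip peak deviation 2–6 m/s² (wrist 3–8 m/s²; both
  free parameters — the source reports no amplitude statistics for these).
- **Gyroscopes**: scaled, phase-shifted companions of the site envelope with
  independent noise (0.05 rad/s); the source gives no quantitative gyro
  ranges, so these channels are qualitative only.
- **Streams**: continuous background (quiet, or alternating quiet/gentle
  walking) with scheduled events. Two stream-only ambiguous activities
  provoke realistic false alarms: `stairs` (repeated heel strikes with hip
  impacts 12–18 m/s², overlapping the fall range) and `lie_down` (a
  sustained posture change with only a soft 10–13.5 m/s² bump — the classic
  bed/sofa false positive). In streams, a fallen subject gets up at the end
  of the 8 s event.

What a green test does and does not establish: the generator reproduces the
*qualitative* structure the published results rely on (hip separates falls
from wrist-dominant ADLs; the wrist alone is ambiguous; unseen ambiguous
activities cause false alarms that user feedback can correct). It makes no
claim of biomechanical fidelity, does not model sensor saturation, drift,
device drop-outs, soft (low-impact) falls, or real inter-device clock skew,
and numeric scores on synthetic data are not comparable to scores on real
recordings.

## Evaluation choices

"Leave-one-out" is interpreted as leave-one-*subject*-out (per-window LOO
would leak trials across splits). Fold confusion counts are pooled before
computing precision/recall/F1/accuracy (micro-average), since single values
per configuration are reported. Undefined ratios are reported as NaN with a
warning, never silently as 0. Display rounding is half-up to 2 decimals.
The ablation covers 4 single-location/single-sensor (SLSS) and 11
multi-location/multi-sensor (MLMS) combinations in a canonical channel
order (wA < wG < hA < hG).

## Desk-scale acceptance experiments

The stochastic acceptance experiments run on one CPU, so they are scaled
down: cohorts of 4 subjects × 2 reps, 15 training epochs, a reduced
d_model = 32 / 2-layer / 2-head architecture, and offline stride 64 (the
streaming stride stays 32 because the 10-probability trigger is calibrated
to ~1 s prediction spacing). The architecture reduction was fixed for
runtime before the experiments were frozen; the orderings under test are
expected to be robust to model size.

At this scale, the headline orderings reproduce: fused wrist+hip
accelerometers match or beat the wrist alone (median LOSO F1 over 5 cohort
seeds), adding gyroscopes does not improve the median F1, and retraining on
user-rejected alarms strictly reduces stream-level false positives in ≥ 4/5
seeds without losing event recall.

One published pattern does *not* reproduce robustly in this synthetic world:
retaining the full TN pool (TN:fall ≈ 30:1, the published imbalance) is
expected to trade recall for precision relative to feedback-only
retraining. Here fall windows carry a strong separable signature (impact
plus posture change at the stated amplitude ranges), so extra easy TN
windows act as regularization and recall often ties or improves. The
corresponding acceptance test asserts only the direction medians
(precision not lower, recall not higher) and is an honest probe of this
boundary; the underlying mechanism in real data — irreducible class overlap
from soft falls and diverse home motion — is deliberately outside the
generator's stated ranges.

## Known limitations

- The NumPy trainer is single-threaded and unoptimized for large cohorts;
  paper-scale (16 × 5) training with the full 128-d architecture is hours of
  CPU time, though all code paths support it.
- Timestamps are integer milliseconds; sub-millisecond timing is not
  preserved.
- The feedback simulator models a truthful, always-responding user; response
  noise and missing feedback are not modelled.
- Checkpoints are NumPy `.npz` archives; no mobile/TFLite export.
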