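# Methods

## Problem and scope

`imugait` implements a complete workflow for pathological gait recognition
(PGR) from body-worn inertial measurement units (IMUs): five sensors
(sternum S, left/right pelvis LP/RP, left/right wrist LW/RW), each
providing a 3-axis accelerometer, gyroscope and magnetometer at 128 Hz.
Five walking patterns are classified: normal (WN), hemiplegic (WH), equine
/ foot-drop (WF), ataxic-cerebellar (WA) and Parkinsonian (WP).  WH and WF
are acquired on either body side but classified without side distinction,
so they are represented twice as often as the other classes — a deliberate
imbalance the evaluation metrics must be robust to.

Because no clinical recordings ship with the package, a synthetic cohort
simulator generates labelled multi-IMU recordings that reproduce the
acquisition protocol and the kinematic cues separating the classes.  All
results quoted in the README are computed on that synthetic surrogate.

## Acquisition protocol emulated by the simulator

Each subject performs 7 task variants (WN, WA, WP, WH-left, WH-right,
WF-left, WF-right), each repeated 4 times by default: 28 repetitions per
subject, 532 recordings for the default 19-subject cohort.  A repetition
is 15 s quiet standing, a straight 7 m walk, and 5 s standing.  The walk
duration therefore varies with the class-dependent walking speed (below),
which exercises the windowing logic with realistically unequal sample
counts.  Half a second at each end of the walk is excluded from the
labelled segment to mimic the manual removal of stand-to-walk and
walk-to-stand transitions.

## Synthetic signal model

Per channel, the walking segment is a cadence-locked sinusoid stack
(fundamental plus two harmonics), a gravity/bias offset, class-specific
modifier terms, and white Gaussian noise (default sd 0.02 in channel
units — the separability dial: raising it degrades classification toward
five-class chance).  Channel phases and relative axis gains come from one global
template shared by all subjects — gait waveforms are biomechanically
consistent across people — with per-subject jitter (sd 0.25 rad) and a
small per-repetition jitter (sd 0.05 rad).  Subjects further carry
log-normal amplitude scales (sd 0.10) and cadence/speed scales (sd 0.05).
Wrist accelerometer/gyroscope channels oscillate at half the step cadence
(arms swing once per stride).  Magnetometers are a static field plus a slow
heading drift, cadence-informative only on the wrists and only weakly, so
that magnetometer-only input is the least discriminative configuration.

Class parameters (defaults, chosen once from the qualitative clinical
descriptions; step cadence in steps/s, speed in m/s):

| class | cadence | speed | distinguishing terms |
|-------|---------|-------|----------------------|
| WN | 1.8 | 1.25 | vigorous symmetric arm swing, almost purely at stride frequency |
| WH | 1.4 | 0.80 | affected wrist amplitude ×0.2 (arm swing asymmetry 0.8); affected pelvis gyro ×1.4 with a circumduction double bump; stiff low-harmonic stride |
| WF | 1.6 | 0.95 | affected pelvis gyro ×1.7 with a pronounced second-harmonic swing bump (compensatory circumduction) |
| WA | 1.1 | 0.65 | lateral pelvis sway noise; stride-to-stride amplitude modulation (0.3, floored so the walk never nears standstill) and cadence wobble (frequency modulation, depth 0.15); per-repetition cadence jitter 0.08; disrupted arm swing |
| WP | 1.0 | 0.50 | 4.5–5.5 Hz wrist tremor (amplitude 0.5); sternum forward-lean bias 1.5; all amplitudes ×0.6 (short steps) |

Determinism: the cohort is a pure function of its configuration, including
the seed; per-repetition random streams are spawned from
`SeedSequence((seed, 2, subject, task, repetition))`.

What the simulator does *not* model: ground-reaction transients, sensor
drift and calibration error, soft-tissue artifact, turning, double-support
timing, or any amplitude statistics of real OPAL recordings.  Passing
tests on this surrogate therefore demonstrate that the pipeline,
training protocol and statistics behave as specified on data whose class
structure is known — not that the classifiers reach any particular
accuracy on clinical data.

## Preprocessing

Pipeline order (fixed): extract the labelled walking segment → per-channel
min-max normalization of that segment to [−1, 1] → sliding windows of 128
samples (1 s) with 50% overlap (64-sample stride) → per-window linear
resampling to the target length (identity at native 128 Hz) → channel
selection.  Segmentation strictly precedes normalization so standing and
transition artifacts cannot compress the walking dynamics' range.

Design choices where the procedure was genuinely open:

* normalization scope is per channel within one repetition's walking
  segment, which prevents amplitude statistics leaking across subjects;
* constant channels map to the range midpoint (0);
* a trailing part-window is discarded, not padded — padding would inject
  artificial statics;
* a segment shorter than one window yields zero windows with a logged
  warning rather than an error;
* every window inherits its repetition's class label and subject id.

Channel layout is canonical and fixed: sensors in the order S, LP, RP, LW,
RW; within a sensor acc, gyro, mag; within a component x, y, z.  The
channel count law `Nch = 3 · n_components · n_sensors` is enforced by the
container types.

## Classifiers

Three 1-D CNNs share the input contract `(Nw, Wl, Nch)`:

* **smCNN-1D** (simplified multi-branch): one branch per IMU component —
  conv1d(128 filters, kernel 5) → ReLU → global average pooling — branch
  concatenation, dense(128) → ReLU → dropout(0.5), softmax.  Batch 256.
* **sCNN-1D** (sequential): the same stack without branch splitting, so it
  accepts single-component input naturally.  Batch 32.
* **mCNN-1D** (multi-branch): a deeper per-component branch —
  conv1d(64, 5) → ReLU → maxpool(2) → conv1d(128, 5) → ReLU → global
  average pooling — then the same head.  Batch 32.

The network engine (convolution via im2col/BLAS, hand-written backward
passes, Adam) lives in `imugait._net` and is float32 throughout.

Training: Adam on categorical cross-entropy; the default learning rate is
1e-3, raised to 4e-3 for smCNN-1D following the standard linear-scaling
heuristic for its 8×-larger batch (otherwise its few optimizer steps per
epoch leave it undertrained within the same epoch budget).  Early
stopping monitors validation **macro** recall — the unweighted per-class
mean, chosen because of the WH/WF over-representation — stops after
`patience` (default 10) epochs without strict improvement, and restores
the best-validation weights; among epochs tied at the best value the
most-trained weights are kept, since extra optimization at equal
validation quality widens decision margins.  Hyperparameters not pinned by the architecture definitions
(optimizer, learning rate, epochs, patience, dropout, the non-smCNN batch
sizes) are conventional defaults and all exposed in `TrainConfig`.
Training, including dropout masks and shuffling, is reproducible for a
fixed seed; across BLAS builds bit-exactness is not guaranteed, which is
why the end-to-end checks assert medians, not loss curves.

## Evaluation protocol

Splitting is subject-wise: validation and test each receive
`round(0.2 n)` subjects, training the remainder — (11, 4, 4) at n = 19 —
and every window of a subject follows its subject.  The partition is
redrawn 10 times (seeds `base_seed + repeat`).  Metrics come from
one-vs-rest confusion counts: accuracy `(TP+TN)/(TP+TN+FP+FN)`, lifted to
the multiclass fraction of correctly labelled windows, and recall
`TP/(TP+FN)` macro-averaged.  Inference time is the wall clock of one
forward pass over a window batch (one untimed warm-up call first); it is
recorded but never asserted against, being hardware-bound.

Paired model comparisons: Shapiro–Wilk on both samples at α = 0.05; if
both pass, a paired t-test, otherwise a Wilcoxon signed-rank test with the
exact null distribution for n ≤ 25.  Zero differences are discarded
(Wilcoxon's original rule); identical samples give p = 1.  Constant
samples, for which the Shapiro statistic is undefined, are routed to the
rank test.  P-values are reported raw; a Holm correction is available but
off by default, since the comparison procedure applies none.

## Problem sizes used for the shipped end-to-end results

The surrogate of the headline experiment runs at a desk scale chosen as
the package's own benchmark configuration: 10 subjects, 2 repetitions per
task (140 recordings, ≈2000 windows), full sensor set, smCNN-1D and
sCNN-1D, 10 repeated splits, ≤30 epochs with patience 8.  The component
ablation reuses the same cohort with accelerometer-, gyroscope- and
magnetometer-only selections.  The label-shuffled control permutes
training labels per repeat and lands at five-class chance (≈0.2).

## Known limitations

* The mCNN-1D layer stack is this package's own definition of "a deeper
  multi-branch CNN"; it preserves the deeper-vs-simplified contrast but is
  not a reproduction of any published network.
* The simulator's separability is a design property, not a claim about
  clinical data; with its default small noise the classes are separable
  by construction, and the noise dial degrades accuracy toward chance.
* Exact Wilcoxon p-values are computed on the non-zero differences; with
  many ties among |differences| the exact distribution is still used, but
  tied ranks make the test conservative.
* Single-CPU float32 training; no GPU path.
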