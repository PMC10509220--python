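# Methods

## Problem and scope

`dynaquery` implements pool-based active learning for two-class medical
image classification, built around a *dynamic query scheduler*: instead of
querying the labeling oracle every Q epochs, the scheduler reads the
training-loss history and queries when learning from the current labeled
pool has become unproductive. The package contains the full experimental
apparatus — dataset splitting, labeled/unlabeled pool bookkeeping behind an
auto-labeling oracle, the preprocessing and augmentation pipeline, a
classifier with metadata fusion, the training engine, the query strategies
and schedulers, evaluation, a hyperparameter-sweep driver, and a synthetic
data generator — so every component is testable end-to-end on one CPU.

## Data model and splitting

Samples are pseudo-unlabeled: every sample has a true class (*included* =
the slice crosses the left pulmonary artery orthogonally through its widest
point; *excluded* = everything else), but the class is reachable only
through the oracle (`Dataset.oracle_label`, used by `oracle_reveal` on a
query and by the evaluator on the label-known validation holdout).
Concealment is interface discipline, not cryptography: iterating the data
never yields a label.

The validation holdout takes an equal number of scans per class:
`min(cap, floor(min(|E|, |I|) / 2))` each, default cap 50. The flooring
keeps the count integral for odd class sizes; the equality keeps the
holdout balanced regardless of the pool's imbalance. Everything else is the
training pool. The labeled pool starts with n = 1 uniformly drawn sample;
n = |pool| is the fully supervised configuration.

## Preprocessing and augmentation

Crop to rows [5H/16, 12H/16), columns [2W/16, 10W/16) (floor-exact,
half-open); bilinear resize to 160 × 200 (align-corners-false convention);
channel-average to grayscale; per-image min–max normalization to [−1, 1]
(a constant image maps to zeros to avoid division by zero — whether the
normalization is per-image or per-dataset was an open choice; per-image
needs no dataset statistics and is what the pipeline's sample-at-a-time
contract implies). Metadata is normalized elementwise by the standard
logistic; the default vector (M = 22) is position (3) + proper Euler angles
(3) + two orientation vectors (6) + slice-location scalar (1) + scout
position (3) + scout orientation (6). M is configurable since real headers
vary.

Augmentation draws, per sample per epoch: rotation U(−5°, 5°), isotropic
scale U(0.95, 1.05), horizontal shear displacing the top edge by U(0, 5)
pixels, brightness and contrast factors U(0.9, 1.1); the affine part is
composed into one bilinear warp about the image center, out-of-field pixels
take the image minimum, and the result is re-clamped to [−1, 1].
Augmentation applies to training samples and to candidates at query-scoring
time (one draw per candidate per query — scoring through the same input
distribution the model trains on), never to validation inputs. A batched
gather-based warp was benchmarked against `scipy.ndimage.affine_transform`
and was slower on the target hardware, so the batch API loops the C warp
per image and vectorizes only the photometric jitter.

## Classifier and training engine

The classifier is a pluggable image backbone whose feature vector is
concatenated with the normalized metadata and passed through dense layers
of 128 and 56 rectified units to two logits. The default backbone
(`tinyconv`) is a compact convolutional network: an 8× average-pool front
end (parameter-free, applied outside the gradient graph and cacheable for
repeated inference), a 3 × 3 convolution with 8 channels, ReLU, 2× max
pooling, flatten (792 features). A large pretrained residual network fits
behind the same `forward/backward/params` contract when one is available;
nothing in the framework depends on backbone size.

The engine is a small numpy layer library with manual backpropagation.
Training uses softmax cross-entropy (natural log; the base-2 logarithm is
reserved for the entropy *query score*, which is defined that way), SGD
with Nesterov momentum 0.95, L2 weight decay 1e-2 on all trainable
parameters, minibatches of min(16, |pool|), and an initial learning rate of
1e-2 decayed ×0.9 by a reduce-on-plateau rule (patience 20 epochs, zero
improvement tolerance, counter reset after each reduction so consecutive
stalls compound). Numerical choices: parameters and activations in float32;
cross-entropy epsilon-clamped at 1e-12; global data-gradient norm rescaled
above 10 (a safeguard against the momentum runaway that a post-query loss
spike can otherwise trigger in single precision — inactive on healthy
steps).

During active learning the plateau replay is scoped to epochs since the
last query: a query changes the training set, so the loss minimum reached
while overfitting a smaller pool is not a meaningful baseline, and without
the scoping the learning rate decays every 20 epochs for the remainder of
the run regardless of actual plateau behavior.

## Query scheduling and selection

Dynamic scheduling fires when either condition holds (checked in this
order, which also names the event in the query log):

1. **SMA**: mean of the last 5 per-epoch losses strictly below 1e-4
   (false while fewer than 5 epochs are recorded);
2. **plateau**: k ≥ 20 epochs since the last query event (initialization
   counts as a query at epoch 0), and mean(most recent ceil(0.25·k) of
   those k epochs) strictly greater than 0.5 × mean(the preceding k − r).
   Both segments are scoped to the k post-query epochs; r = ceil(0.25·k)
   guarantees a non-empty recent segment at the k = 20 gate.

Baselines: `fixed:Q` queries exactly when the gap since the last query
equals Q; `random_timing` queries each epoch with probability 1/Q.

Selection scores a uniform random subset of min(500, |U|) unlabeled samples
by base-2 entropy of the predicted class distribution and takes the top
L = 1 (ties broken by ascending sample id for cross-platform determinism);
a random-selection variant picks uniformly from the same candidate set at
the same query times, isolating the value of the entropy score. The outer
loop stops when the query budget is exhausted (or the pool is empty) and
the validation accuracy has not improved for 100 epochs, or at
`max_epochs`. Every stochastic concern (split, pool initialization, model
initialization, shuffling/augmentation, candidate choice, scoring
augmentation, random timing, random selection) draws from its own stream
spawned from the master seed, so changing one knob never perturbs another
concern's draws.

## Evaluation

Predicted class is the argmax probability; an exact 0.5/0.5 tie predicts
*excluded* (conservative inclusion, deterministic). *Included* is the
positive class. Single-run binomial quantities (accuracy, sensitivity,
specificity, precision, NPV) carry Wilson score 95% intervals — the CI
method was an open choice; Wilson behaves well at the small validation
sizes used here. Across-replicate summaries (best accuracy, epoch at best)
carry t-intervals over seeds, matching the replicate-level variation such
summaries describe. The accuracy-vs-labels table reports, for each labeled
pool size reached, the maximum validation accuracy attained at that size.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
MRI physics. *Included* images contain a bright near-circular ellipse
centered in the crop window over Gaussian background noise; *excluded*
images perturb it by one of three mechanisms — axis-ratio elongation (an
oblique cut), center displacement out of the crop window (wrong slice
position), or heavy blur (poor quality) — with magnitude proportional to
(1 − difficulty). At difficulty 0 the classes are trivially separable; at
difficulty 1 the class-conditional distributions coincide exactly (the
excluded generator consumes its extra random draws after the shared ones,
so stream-for-stream the pixels are identical). Metadata is
class-conditional Gaussian with unit variances and mean separation
`metadata_separation · (1 − difficulty)` along a fixed direction. Defaults:
120 included / 62 excluded (the ~2:1 imbalance of the cohort the task comes
from, at desk scale), 64 × 64 raw images (the pipeline is size-agnostic;
small images keep the suite fast), difficulty 0.4, metadata separation 3.0
(chosen so that metadata alone supports a clearly-above-chance but
imperfect classifier at the default difficulty, as acquisition geometry
does for the real task), label noise 0.

What passing tests on this generator do *not* show: robustness to scanner
variation, intensity non-uniformity, anatomical confounders, or annotator
noise — real-data properties the ellipse family does not emulate. They do
show that the scheduler, selection, pools, training, and evaluation
machinery behave as specified under controlled separability.

Loss-trace generation (`exponential_decay`, `plateau_after`,
`noisy_constant`, `piecewise`, each with optional Gaussian noise clamped at
zero) exists to exercise the scheduler in isolation; the plateau-after
trace is read with a query event at the plateau start, which is the
configuration whose first plateau firing lands exactly 20 epochs later.

## Experiment scales

The shipped experiment configurations are desk-scale: the label-efficiency
comparison uses the 182-sample default dataset, budget 30, `max_epochs`
700 with stop patience 100 (the dynamic scheduler typically spends its
budget between epochs 400 and 650 here, leaving room to consolidate), 10
replicate seeds per arm, and a supervised ceiling averaged over 2 seeds ×
100 epochs. The smoke test trains fully supervised on difficulty-0 data for
100 epochs.

## Known limitations

- The plateau condition never fires again once a run's post-query loss
  spike dominates the window mean (k grows without bound), so dynamic runs
  on some seeds acquire fewer labels than their budget; this is a property
  of the published rule under a loss floor above the SMA threshold, and the
  shallow fusion head's weight-decay equilibrium keeps the floor near 1e-3
  once the labeled pool exceeds a handful of samples.
- The engine is CPU-oriented and deliberately small; it is not a general
  deep-learning framework, and the default backbone under-fits data that a
  pretrained residual network would master.
- Query batches larger than one use plain top-k entropy without diversity
  correction.
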