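# Methods

## Overview

`plantargait` implements a graph-convolutional LSTM for short-horizon
prediction of plantar force fields and fall-direction classification
from a 40-unit tactile sensor array mounted in the insoles of a walking
(nursing) aid user. The pipeline is:

1. **Sensor layout.** Five flexible tactile sensors per foot model
   (toe, first metatarsal, lateral metatarsals, medial heel, lateral
   heel), each an eight-unit 2x4 grid at 10 mm pitch, giving 40 sensing
   units. Each unit reports a 3-axis force sample `(f_x, f_y, f_z)` at
   50 Hz, with the normal channel bounded by the 60 N sensor range.
2. **Tactile graph.** Units are vertices. Within a sensor, units are
   fully connected; across sensors, each unit connects to its nearest
   units in every other sensor, which keeps the 40-vertex graph
   connected. The graph is undirected with a zero diagonal.
3. **GCN spatial encoding.** Each frame `X in R^{40x3}` passes through
   `sigma(L_sym X W)` where `L_sym = D^{-1/2}(A + I)D^{-1/2}` is the
   symmetric normalized adjacency with self-loops and `sigma` the
   logistic sigmoid. Self-loops guarantee positive degrees; `L_sym` is
   symmetric with spectrum in `[-1, 1]`.
4. **LSTM temporal encoding.** The per-frame GCN features are flattened
   (40 units x output width) and fed to a single gate-level LSTM. Each
   gate weight is `H x (H + M)` acting on the concatenation
   `[h_{t-1}, x_t]`; the forget-gate bias is initialized to 1.
5. **Shared multi-task head.** The final hidden state passes through a
   sigmoid shared layer of `S` nodes, then two linear heads: a
   regression head (`S x 120`) predicting the next 40x3 force frame and
   a classification head (`S x 5`) scoring the walking states
   {normal, forward fall, backward fall, left fall, right fall}.
6. **Autoregressive rollout.** Multi-step prediction feeds each
   predicted frame back into the history window, producing frames and
   state decisions at 0.2 s intervals up to a 5-step (1 s) horizon.

## Training

All gradients are hand-derived reverse-mode (backpropagation through
time) in NumPy and validated against central finite differences at
relative error below 1e-6. Optimization is Adam with L2 weight decay
applied to weight matrices only (not biases). The joint loss is

```
L = MSE(frame_pred, frame_true) + alpha * L_cls
```

with `L_cls` either the MSE against the one-hot state (`l2_both`,
default) or the softmax cross-entropy (`l2_plus_xent`). Inputs and
regression targets are normalized by the 60 N sensor range, so reported
MSE is on the dimensionless `[0, 1]` force scale.

### Learning-rate choice

The reference description pairs the joint L2 objective with a learning
rate of 1e-8, which does not move Glorot-initialized parameters
measurably within the stated epoch budget on normalized inputs. The
package default is 1e-3 (with Adam), which trains to convergence; the
documented 1e-8 remains available via `ModelConfig(learning_rate=1e-8)`
or the CLI flag `--published-lr` for faithful replication.

## Synthetic gait generator

No public dataset accompanies the sensing hardware, so the package
ships a generator with explicitly stated mechanics:

- **Normal walking** is a periodic heel-to-toe load wave: each sensor
  region has a fixed phase in the gait cycle (heel ~0.08-0.12,
  metatarsals ~0.45-0.50, toe ~0.72) and a Gaussian activation bump.
  Peak regional loads are light (10-18 N), consistent with partial
  weight-bearing by a user leaning on a nursing aid.
- **Falls** are sustained, direction-specific static load patterns
  approaching the 60 N range (e.g. forward falls load toe and
  metatarsal regions at 70-80% of range while unloading the heel).
  After a uniformly drawn onset frame (20-30), the signal ramps from
  the periodic pattern to the static pattern over 3 frames and holds.
- **Tangential channels** (`f_x`, `f_y`) are proportional to the signed
  rate of change of the normal force, capped at 12 N; lateral falls
  flip or boost the mediolateral component.
- **Ground conditions** (ceramic reference, wood, cement, stairs,
  slope) perturb the generator via a noise multiplier, amplitude scale,
  phase jitter/shift, and a pattern-blend coefficient that dilutes the
  directional fall signature toward a direction-neutral mean. Shifted
  conditions are strictly harder than the ceramic training condition.
- **Reproducibility.** Every collection is regenerable in isolation:
  sequence `i` of a dataset with master seed `s` uses
  `SeedSequence([s, i])` reduced below 2^31.

### Generator limitations

- Loads are stationary per region; there is no center-of-pressure
  trajectory within a sensor, no double-support asymmetry, and no
  inter-stride drift.
- Falls are stereotyped static end-states rather than measured fall
  biomechanics; the 3-frame transition is a modeling choice, not a
  measured fall duration.
- Noise is i.i.d. Gaussian per unit and frame; real sensors exhibit
  drift, hysteresis and crosstalk.
- The generator was calibrated (walking loads, fall patterns,
  transition length) against a nearest-centroid separability oracle,
  before any model-based acceptance checks, so that the reference
  condition admits >= 95% frame-level accuracy for a linear rule.

## Evaluation

Classification is scored with macro-averaged one-vs-rest precision,
recall and F1 in percent (classes without support are excluded from the
macro average; zero-denominator classes score 0 with a warning).
Regression is scored with MSE on the normalized force scale. Reports
are per rollout step, exported as CSV/JSON plus per-step confusion
matrices.

## Numerical choices

- Float64 throughout the model; datasets stored as float32 (HDF5,
  gzip) with int8 labels.
- Numerically stable logistic sigmoid (split by sign) and softmax
  (max-shifted).
- Checkpoints are NumPy `.npz` archives with a JSON metadata record
  including the sensor-layout hash; loading refuses a checkpoint whose
  layout hash does not match the requested layout.
- Named random substreams (`SeedSequence([seed, crc32(name)])`)
  decouple initialization, shuffling and data sampling so each is
  independently reproducible.
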