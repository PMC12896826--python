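# Methods

## Sensor frames

The unit of classification is a *single-frame* summary of a 10 s sensor
window: nine IMU per-axis means (accelerometer, gyroscope, magnetometer at
1 Hz) plus the GPS displacement between the fixes bracketing the window.
Displacement uses the haversine great-circle distance with Earth radius
6371.393 km; for the ≤100 m in-window movements this is numerically
indistinguishable from planar distance but stays correct at any
separation. IMU units are arbitrary sensor units — standardization (below)
makes the downstream pipeline unit-free, so no unit checking is enforced.

## Preprocessing chain

1. **SMOTE.** Minority classes are oversampled to the majority count by
   interpolation `x + u (x_nn − x)`, `u ~ U(0,1)`, with `x_nn` drawn from
   the k = 5 nearest same-class neighbors (Euclidean, on raw features).
   k = 5 is the conventional default; the neighbor metric runs on
   unstandardized features because oversampling precedes standardization
   in the reference order.
2. **Split.** Random 7:3 train/test partition, stratified by class by
   default (plain random available). When a search needs a reward set, a
   validation fraction is carved out of the training side.
3. **Standardize.** Per-feature mean and *population* (1/n) standard
   deviation computed on the training partition only and applied to all
   partitions. Constant features would produce σ = 0; σ is floored at
   1e-8, so they standardize to exactly zero rather than dividing by zero.

The default order is SMOTE → split → standardize. Oversampling before
splitting lets synthetic points leak information across the partition
boundary; the leakage-free alternative (split first, oversample the
training side only) is supported via `smote_before_split=False` and is the
right choice when measuring generalization carefully. Both orders are
tested.

## Synthetic herd generator

Real collar recordings are not publicly deposited, so the package
generates class-conditional windows and runs them through the same frame
assembly as real data. Per behavior the generator draws: a window-level
IMU mean (class posture plus animal/posture jitter), 1 Hz sample noise,
and a displacement from a zero-truncated normal. The defaults encode the
qualitative structure of grazing-cattle data:

- displacement scale separates locomotion: Walking ~10 m/10 s ≫ Grazing
  ~2 m ≫ Standing/Lying ~0.5/0.2 m;
- accelerometer means encode posture: head-down Grazing, horizontal
  Lying, upright Standing/Walking, with Standing placed between Grazing
  and Lying and matched noise scales so the Standing↔Grazing and
  Standing↔Lying confusions seen in collar studies survive in the
  synthetic draws;
- gyroscope level encodes activity (and, in the 6-class scheme, separates
  ruminating from resting);
- class proportions are imbalanced (4-class default 40/30/20/10% with
  Walking rarest), following typical grazing time budgets, so SMOTE is
  genuinely exercised.

What the generator does **not** emulate: temporal autocorrelation between
consecutive windows, individual-animal fixed effects, sensor drift and
outliers, GPS multipath error, and label noise. Consequently the synthetic
task is cleaner than field data — the ~95–97% accuracies reached here
overshoot the ~94% scale reported for real recordings — and passing tests
demonstrate correctness of the pipeline and the compression machinery, not
field-level performance.

Everything is driven by one root seed; per-stage substreams are derived
with `numpy.random.SeedSequence.spawn`, so a pipeline run is reproducible
end to end.

## S-ResNet

The classifier treats the 10 features as a one-channel sequence of length
10. Architecture: Conv(1→32, k=3) + BN + ReLU; two residual blocks
(Conv k=3 + BN + ReLU, Conv k=3 + BN, added to a Conv k=1 + BN shortcut,
ReLU) widening to 64 then 128 channels; global average pooling over the
length axis; FC 128→64; FC 64→C. Scores are pre-softmax logits; softmax is
applied only at prediction time. No ReLU sits between the two head layers
by default (`head_relu` toggles it). Dropout and weight decay are not
used.

Choices the architecture description leaves open, fixed here:

- **Padding/stride:** stride 1 with length-preserving ('same') zero
  padding everywhere. Residual adds require equal lengths, and this is the
  convention under which the MAC totals below reproduce.
- **Batch norm:** momentum 0.1, eps 1e-5; evaluation uses running
  statistics.
- **Initialization:** fan-in-scaled uniform, seeded.
- **Precision:** training runs in float32 by default (`dtype` parameter);
  gradient-correctness tests run the engine in float64.

Training: Adam, learning rate 0.001, cross-entropy, batch size 128,
100 epochs by default. Fine-tuning after pruning reuses the identical
loop starting from the surviving weights.

### MAC accounting

`count_macs` prices a spec as kernel multiplies plus bias accumulations
over conv and fully connected layers only: conv = `out·in·k·L_out +
out·L_out`, fc = `out·in + out`, with `L_out = input_length` (stride 1,
same padding). BN, activations and GAP are excluded. Under this convention
the default widths cost 1,039,686 MACs (6-class head) and 1,039,556
(4-class), both printing as 1.040M. Deployment toolchains that count
auxiliary ops report slightly different totals (e.g. 1041.44K); that
convention is intentionally not reproduced. The counter is verified
against a brute-force per-output-element enumerator.

## Pruning environment

Five coupling groups partition the prunable channels: (1) inputs of
block1's conv_a and shortcut ⇒ conv1 filters; (2) input of block1.conv_b ⇒
block1.conv_a filters; (3) inputs of block2's conv_a and shortcut ⇒
block1.{conv_b, shortcut} filters jointly; (4) input of block2.conv_b ⇒
block2.conv_a filters; (5) input of FC1 ⇒ block2.{conv_b, shortcut}
filters jointly. conv1's input is the raw frame (excluded from pruning),
and FC2's input is the fixed 64-wide head. The residual adds force joint
producer pruning in groups 3 and 5; importance for those shared decisions
sums squared norms across both consumers' weight slices.

Executing retention R on a group keeps the `ceil(R·c_in)` channels with
the largest L2 norm (ties to the lower index, kept indices sorted, so
R = 1 is bit-identical), floored at `ceil(0.2·c_in)`. Retention is the
kept fraction `c_in′/c_in` throughout — the inverted "1 − c_in′/c_in"
phrasing that sometimes appears for this quantity is treated as an
erratum.

**Budget enforcement.** The optimization constraint (pruned/original MACs
≤ R_target) is enforced by action clamping: before executing group *l*,
the largest kept count is found (binary search on the monotone width →
MAC map) such that pruning all remaining groups at the floor still meets
the budget; infeasible budgets fail at episode start. This makes the
budget a hard guarantee of every finished episode rather than a soft
penalty, and is precisely why the state carries `reduced` and `rest`.

**State rows.** `reduced` = MACs removed by earlier decisions; `rest` =
MACs of consumers of later groups at current widths (zero at the last
decision); `R_{l-1}` the previous executed retention. For FC1 the conv
fields degenerate to k = 1, stride 1. The six static columns are min-max
scaled over the five groups (known up front), the per-channel columns
within the current state, and the MAC columns by the original total —
a deterministic variant of per-episode min-max scaling that needs no look
at future states.

**Reward.** Zero except at the terminal step, where it is held-out
accuracy × `reward_scale`. Both published conventions for the scale
appear (0.01 and 0.1); the default is 0.01 and the parameter is exposed.
Accuracy is computed on a validation split never used for weight updates,
optionally subsampled (deterministically, once) to bound episode cost; no
fine-tuning happens inside the search — fine-tuning is applied only to
the selected best strategy.

## GNN–TD3 agent

Channels are nodes; edges connect each channel to its k = 5 most
cosine-similar channels by flattened weight slice, symmetrized, plus self
loops ("closely related channels" read as weight similarity — a cheap,
deterministic rule). The GCN uses the symmetric normalization
D^{-1/2} A D^{-1/2} of the self-looped adjacency.

Actor: GCN 11→400 → ReLU → GCN 400→300 → ReLU → GCN 300→1 → mean pool →
sigmoid (outputs strictly inside (0,1); mean pooling keeps the scale
independent of layer width, where sum pooling would saturate the sigmoid
differently per layer). Critics: GCN 11→400 + mean pool on the state,
affine 1→400 on the action, fused by elementwise sum, then 400→300→1 with
ReLU between. Twin critics are architecturally identical and
independently initialized; target networks start as exact copies.

TD3 specifics: exploration phase (episodes ≤ T1) samples retentions
uniformly on [0.2, 1]; afterwards actions are truncated-normal around the
actor output with scale δ1·decay^(episode−T1). Targets are
`r + γ·min(Q1′, Q2′)` at the smoothed action `clip(actor′(S′) + ε, 0.2,
1)` — the smoothing noise is clipped into the valid retention range, and
the bootstrap term is dropped at terminal transitions (episodes are
finite-horizon). Critics are regressed to the shared target each update;
the actor ascends Q1 and targets soft-update with τ every
`policy_delay` = 2 steps. One update runs per episode after the
exploration phase, mini-batch 64 sampled without replacement from a FIFO
buffer.

Defaults stated by the reference compression setup: 100 exploration + 500
exploitation episodes, retention floor 0.2, τ = 0.01, batch 64,
actor/critic learning rates 0.001. Defaults this package had to choose:
γ = 0.99, δ1 = 0.25, δ2 = 0.1, buffer capacity 10,000, noise decay
0.99/episode, k_nn = 5 — all exposed in `TD3Config`. A single actor is
shared across all five decisions (one policy, five states per episode).
Search runs checkpoint every 50 episodes and are resumable.

## Metrics

Accuracy is trace/total of the multiclass confusion matrix; sensitivity
and precision are per-class one-vs-rest TP/(TP+FN) and TP/(TP+FP). A
per-class one-vs-rest accuracy ((TP+TN)/total) is reported separately
under the name `ovr_accuracy`, since per-behavior "accuracy" in this
literature usually means exactly that and it need not equal the overall
accuracy. Zero-denominator ratios are reported as missing (None), never
as 0, to avoid silently biasing averages. Cohen's kappa uses
marginal-product expected agreement, with κ defined as 1 when both
labelings are constant and identical. Repeated-experiment aggregation
reports mean ± population std over the declared seeds in the
"x% (±y%)" style; the ± value is a standard deviation, not a standard
error.

## Problem sizes used in the tests

The test suite exercises the full pipeline at sizes a single CPU handles
comfortably: the retention experiment trains the 4-class model on the
default n = 4000 synthetic set for 12 epochs (chosen by calibration: the
generator's task is clean enough that 12 epochs reaches ~97% test
accuracy, comfortably above the 90% floor), searches 60 episodes (20
exploration) at R_target = 0.5 with the reward evaluated on 512 validation
frames, and fine-tunes 20 epochs, across 5 seeds. The toy-environment
recovery uses a 2-decision environment with 20 channels per group, so the
0.05-action grid is exactly enumerable. Budget guarantees are checked over
500 random-policy episodes per target ratio.

## Known limitations

- Single fixed architecture family: the coupling groups and width
  bookkeeping are specific to the two-block S-ResNet; pruning arbitrary
  residual networks would need a generic graph tracer.
- The numpy training loop is single-threaded and CPU-bound; it is sized
  for frames of 10 features, not ImageNet-scale searches.
- Terminal-reward evaluation reuses the dense model's batch-norm running
  statistics after surgery; with aggressive pruning these are biased until
  fine-tuning recalibrates them (visible as the pruned-before-finetune
  accuracy dip).
- SMOTE-before-split (the default, matching the reference order) leaks
  synthetic neighbors across partitions; use the leakage-free order for
  honest generalization estimates.
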