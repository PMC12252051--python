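# Methods

This note documents the models and procedures gaitlens implements, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish about real data.

## Skeleton schema and regions

Skeletons are the 18-joint COCO layout (nose, neck, shoulders, elbows,
wrists, hips, knees, ankles, eyes, ears) — a full-body key-point set
without fingers or toes, whose fine motion adds variance but little
gait information. Six regions partition the joints for reporting: head
{nose, eyes, ears}, torso {neck, hips}, and one arm/leg group per side
(shoulder–elbow–wrist; knee–ankle). Assigning the hips to the torso is a
convention, not an anatomical necessity; `JointSchema.region_map` is a
plain dict and can be overridden, as can the bone edges. The coordinate
convention is right-handed, y-up, z depth; units are arbitrary but must be
consistent within a recording (normalization removes scale).

## Synthetic gait generator

The generator is a parametric kinematic model, not a biomechanical
simulation. Each subject draws, from a seeded stream: limb lengths (torso
≈ 0.5 units ≈ 0.5 m), a gait period within ±8% of the configured
`cycle_period` (default 7 frames at 10 Hz — the coarse sampling regime in
which 7-frame cycle instances arise), a stride length (speed =
stride/period, so cadence changes do not imply implausible strides), a
global phase, and oscillation amplitudes. Limb trajectories are
phase-offset sinusoids about a steady walking translation: legs antiphase
left/right, arms antiphase with the same-side leg. The upper body carries
physiological motion of its own — lateral trunk sway at stride frequency,
head nod at step frequency, pelvic list and fore–aft pelvic rotation
(antiphase per side, cancelling exactly at the mid-hip) — because a
skeleton whose head and pelvis are rigidly welded to the root has
zero-variance joints, and inverse-variance importance is meaningless for
them. Default key-point noise (σ = 0.005 units ≈ 1% of torso length) and
occlusion rate (1% of joint-frames) emulate a mid-quality pose estimator.

Pathologies transform the model's parameters, so severity 0 is exactly the
identity and the affected joint set is known ground truth:

| kind | transform | affected region |
|---|---|---|
| `limp_left/right` | affected leg's amplitudes ×(1 − 0.6·s); phase delayed by 0.5·s rad | one leg |
| `shuffle` | step height ×(1 − 0.7·s) both legs; cadence ×(1 + 0.3·s) | both legs |
| `weighted` | walking speed ×(1 − 0.4·s); arm swing ×(1 − 0.5·s) | both arms |

The arm swing is driven by the *base* gait rhythm, so a leg-only pathology
does not drag the same-side arm along — keeping the perturbation confined
to the region the explanation metrics are expected to recover.

Occlusions displace a joint by 5 torso lengths in a random direction,
re-drawn until the sentinel is at least 2 torso lengths from every
connected key-point (including simultaneously occluded neighbors): the
sentinel's contract is implausibility, and without the re-draw two adjacent
dropouts can land near each other and mimic a plausible bone. The
uncorrupted positions and the occlusion mask are retained in
`SkeletonSequence.meta` as the repair oracle.

**What passing tests on this generator do not show:** robustness to
marker-swap errors, camera-view-dependent depth noise, non-stationary gait
(turning, stopping), overlapping pathologies, or acted/real pathological
kinematics. The generator's role is to provide cohorts whose class
signature and affected region are known exactly.

## Pre-processing

Fixed order: outlier reset → denoise → normalize → velocities → segment.

* **Outlier reset.** A joint-frame is outlying when its distance to every
  schema neighbor exceeds `outlier_bone_factor` (default 3) times the
  smaller of that bone's median length over the sequence and the median
  torso length. The absolute torso-scale cap exists because a joint
  displaced consistently corrupts its own bone's median — by construction
  of the median, no rule of the form "length > k × own median in all
  frames" can ever fire. Flagged frames are linearly interpolated in time
  from the nearest clean frames of the same joint; sequence ends copy the
  nearest valid frame (with a one-frame-of-motion error bound, which is why
  repair accuracy is specified for interior frames). A joint flagged in
  every frame raises `UnrecoverableJointError`.
* **Denoise.** Centered moving average per joint/axis (default width 3,
  edge-padded). Width w attenuates a sinusoid of frequency f by
  sin(πfw)/(w·sin(πf)); at 7-frame cycles this is ≈ 25% at the stride
  frequency, applied uniformly to all sequences, so class contrasts are
  preserved.
* **Normalize.** Each frame is centered on the mid-hip; the whole sequence
  is scaled uniformly so the median neck-to-mid-hip distance equals
  `normalization_target` (default 1). This removes global translation and
  subject scale — verified end to end as an invariance (≤ 1e-6).
* **Velocities.** Forward difference `x[t+1] − x[t]`; row t indexes the
  t→t+1 transition.
* **Segmentation.** `heel_strike` (default) detects cycle starts as local
  maxima of the left-minus-right ankle displacement projected on its
  dominant horizontal direction (sign fixed so the axis's largest component
  is positive), then linearly resamples each cycle to exactly
  `cycle_length` = 7 frames. `fixed_stride` takes non-overlapping 7-frame
  windows. Both exist because variable-length cycles can be cropped or
  resampled and neither choice is canonical; resampling preserves phase
  alignment and is the default.

## ST-TAGCN

Each of the 3 blocks (channel widths 64/128/256 by default; the reduced
8/16/24 configuration is used throughout the tests) applies:

1. spatial graph convolution `H = Â X W` with
   `Â = D^{-1/2}(A + I)D^{-1/2}` over the skeleton bones,
2. multi-head scaled dot-product self-attention across the 7 frames,
   independently per joint (temporal mixing never crosses joints; spatial
   context enters only via step 1),
3. residual connection (1×1 projection when widths differ) and ReLU.

The head projects the last block's channels to `embedding_channels` = 3
per node with a learned per-node 1×1 projection — restoring the 18×7×3
input shape — then flattens into a small fully connected classifier.
Training the projection jointly with the classifier makes the extracted
18×7×3 latent arrays class-discriminative while keeping them node-aligned;
an "embedding locality" property (perturbing one joint's input moves that
joint's embedding row most) is verified on trained models in the tests.

Training: SGD with momentum 0.9, cross-entropy, default 120 epochs, lr
0.001, batch 128, 70:20:10 split, 5 folds. Splits are grouped by subject
(a subject never straddles splits) and checked for class coverage;
`StratificationError` otherwise. A global gradient-norm clip (default 5)
guards against the occasional exploding step at the larger learning rates
used in reduced runs. With a fixed seed and single-threaded BLAS, loss
curves are bitwise reproducible.

The network runs on a ~200-line reverse-mode autodiff engine over NumPy
(`gaitlens.nn.autograd`) — broadcast add/mul, batched matmul, relu,
reshape/transpose, softmax, fused softmax cross-entropy — gradient-checked
against central finite differences to 1e-5 relative error. At 18 nodes × 7
frames the matmuls are far below the scale where a deep-learning framework
earns its complexity.

## Per-joint PCA

For each (joint, channel), the 7 temporal values across the *fit
population* are the features and instances the samples; only the first
principal component is kept (loading sign fixed: largest-magnitude element
positive). One number then summarizes each joint-channel's whole-cycle
behavior, giving the 18×3 embedding. Fitting per population (rather than
within each instance) is what makes explained-variance ratios a dataset
property; the per-instance variant is available
(`fit_joint_pca_instance_mode`) for comparison. PCA is fitted on the
training fold only and applied everywhere, so clustering evaluation never
sees fit leakage. `variance_report` flags (joint, channel) pairs whose
first component explains < 50% of variance — the working threshold for
"one component is enough".

## Clustering and evaluation

K-means (k-means++, best of `n_init` = 10 restarts) with user-supplied k —
the method needs to be told how many pathology classes to expect; a
silhouette table is provided as a diagnostic only. Embeddings are
clustered **on their native scale** by default: per-dimension z-scoring
was measured to inflate near-constant (dead-ReLU or noise-only) embedding
dimensions until they dominate the distance metric, collapsing matched
accuracy from 1.00 to 0.56 on separable synthetic cohorts; the
`standardize=True` flag retains the other behavior.

The regular cluster is the one holding the majority of a user-supplied
reference set of known-regular instances — the only supervision in the
whole explanation stage. Cluster→class evaluation uses maximum-weight
bipartite matching on the contingency table (majority voting can assign
one class to two clusters; matching cannot), with accuracy and macro-F1
over the matched pairs.

## Explainability metrics

Feature granularity: each joint's embedding 3-vector is one feature —
trace variance, 3×3-covariance Mahalanobis, Euclidean centroid gap. A
54-scalar mode (per-axis scores summed back per joint) exists for
sensitivity analysis.

* **Scaling.** `explain_clusters` z-scores every embedding dimension over
  the population before computing statistics (`feature_scaling=
  "population"`). Inverse-variance importance compares features against
  each other and is only meaningful on a common scale: raw first-component
  scores span three orders of magnitude in within-cluster variance across
  joints, and without scaling the lowest-variance joints win regardless of
  whether they carry any between-cluster signal. Overlap is
  scale-invariant either way; the option `"none"` scores raw values.
* **Overlap.** Strict inequality in the Mahalanobis comparison: exact
  distance ties count as non-overlapping, so two identical clusters score
  O = 1 — flagged with a warning, since importance is meaningless there.
  Each cluster's own regularized covariance (ε = 1e-6 × mean diagonal) is
  used rather than a pooled one.
* **Variance floor.** Degenerate features (single-instance clusters,
  identical points) use σ² = 1e-12 with a warning; 1/σ² stays finite but
  the score is flagged as not meaningful.
* **Confidence** can exceed 1 for instances beyond a centroid; values are
  reported unclamped (clamping would hide exactly the cases — confident,
  far-out instances — the metric is meant to surface).
* **Severity** normalizes an instance's distance-to-regular-centroid by
  the mean over *all other abnormal instances* (pooled across abnormal
  clusters); a per-cluster-only normalization is an easy variant but the
  pooled one lets severities be compared across clusters. Severity of the
  regular cluster's own instances against the abnormal normalization is
  reported as a baseline the abnormal clusters should exceed. With fewer
  than two abnormal instances severity is undefined (NaN, with a warning).
* **Region weights.** Default head 0.5, torso 1.0, arms 1.0, legs 1.5 —
  locomotion-bearing regions matter more to gait reading than the nearly
  rigid head. The weights are clinical priors, fully user-configurable,
  and enter before the softmax; ranks tie-break by canonical region order
  with a warning.

## Problem sizes used in tests and the acceptance script

Reduced configurations keep full-pipeline checks fast while preserving the
architecture: 6–8 subjects × 140 frames per recording (~230–300 gait
cycles per cohort), channel widths 8/16/24, 2 attention heads, 25–30
epochs at lr 0.02, batch 32. The pathology-recovery check runs 20 seeded
replicates of the whole pipeline; the clustering-ordering check runs 5
seeds of a 3-class cohort; both finish in minutes on one CPU. The repair-
accuracy check uses 20-frame cycles at 30 Hz — the raw-capture regime
where linear interpolation across a dropout is a fair ask.

## Known limitations

* The temporal-attention block is a concrete re-specification of the
  published idea (per-joint scaled dot-product attention); the original's
  exact formulation and hyperparameters are not public, so numeric parity
  with it is not claimed.
* K-means requires the number of pathology classes; badly chosen k
  degrades both clustering and (through degenerate clusters) the metrics.
* DimWise's 1/σ² term rewards feature constancy; on embeddings with
  heterogeneous noise floors the population scaling above is load-bearing.
* The graph convolution leaks class signal into neighbors of affected
  joints (visible as the torso ranking second for a leg pathology — the
  pelvis borders the leg); region ranks, not raw joint scores, are the
  intended reading granularity.
* Severity is a relative measure within the observed abnormal population,
  not an absolute clinical scale.
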