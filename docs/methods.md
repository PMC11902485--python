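# Methods

This note documents the models, parameters and numerical choices behind
`neoseg`, and what the synthetic experiments do and do not demonstrate.

## Intensity standardization

MRI intensity units are arbitrary and drift between acquisitions, so a
network trained on raw values would mostly learn scanner idiosyncrasies.
We use percentile-landmark standardization (the Nyúl-style scheme): for
each record and modality the foreground 25th/50th/75th percentiles are
pivotal landmarks, flanked by 1st/99th outer anchors; the cohort reference
scale is the arithmetic mean of each landmark over the *training* records
of the current fold, and a record is mapped by the monotone piecewise-linear
function sending its landmark k exactly onto reference anchor k, clamped
onto the outer reference anchors beyond the record's outer anchors.

Choices the underlying scheme leaves open, and how we resolved them:

- **Foreground rule.** Voxels with intensity > 0; air is exactly 0 in our
  data model. Configurable (`nonzero`, `all`, or a callable).
- **Outer anchors at the 1st/99th percentiles**, not absolute min/max:
  a handful of extreme voxels would otherwise swing the outermost linear
  segments. Configurable.
- **Foreground-only mapping.** The transfer function is applied to
  foreground voxels; air passes through unchanged. Mapping air as well
  would clamp it onto the low reference anchor, destroying the
  foreground/background distinction and with it the idempotence of the
  procedure. Since every foreground value exceeds every background value
  under the default rule, the overall voxel map remains monotone.
- **Quantile estimator**: linear interpolation between order statistics
  everywhere (landmarks and cohort summary tables alike).
- **Separate scales per modality** (T1 and T2 are standardized
  independently).

A structural caveat: standardizing a volume and re-estimating its
landmarks does not return the reference anchors *exactly* — the quantile
of mapped values differs from the mapped quantile by the order-statistic
spacing wherever the quantile position falls between two order statistics
that straddle a kink of the transfer function. The residual scales as
1/(number of foreground voxels): measured ≈ 4e-5 on a 32×64×48 phantom
(~30k foreground voxels) and < 1e-6 at the full 112×192×144 acquisition
geometry. Tests assert idempotence and cross-record landmark alignment at
tolerances matching this discretization scale.

**Void filling.** Dropout voxels (validity mask false) are repaired by
iterated 3×3×3 valid-neighborhood medians: each sweep fills every void
with at least one valid neighbor; freshly filled voxels count as valid
from the next sweep, so pockets close rim-inward. The local median is
deterministic, edits only flagged voxels, and inserts only values from the
local intensity distribution, which keeps the histogram — and hence the
landmarks — essentially intact. It is our concrete choice for repairing
sporadic voids; any histogram-preserving local interpolant would do.

## The (2+1)D U-Net

Four encoder levels with filter counts 65/32/16/8 (the reference design
uses 65, not 64, at the top level — kept as published), a 4-filter bridge,
a mirrored decoder (8/16/32/65 bottom-up), and a 1×1×1 softmax classifier
over 4 classes. Every convolution is a (2+1)D pair: an in-plane 1×3×3
convolution followed by an across-slice 3×1×1 convolution, each with its
own ELU (α = 1.0), both carrying the block's full filter count — there is
no intermediate-channel bottleneck, unlike the midplane formula common in
the video literature. Block layouts:

- encoder: pair → BN → dropout(0.2) → pair → BN → (skip tap) → 2×2×2 max-pool;
- bridge: the encoder body without pooling, at 4 filters (two full pairs —
  the published layer table is followed where the prose enumerates only
  three convolutions);
- decoder: 2×2×2 transpose convolution (stride 2, ELU) → concatenate the
  level's skip tap → pair → BN → dropout → pair → BN.

Whole volumes are processed as a batch of one; no patching. Input channels
default to 6: the published input size 112×192×144×6 for two modalities is
interpreted as each modality replicated ×3 (the image-as-RGB convention);
`stack_modalities(..., replication=1)` gives the economical 2-channel
variant used in the scaled-down profiles.

Implementation: layers, backpropagation and ADAM are written directly on
numpy arrays (channels-last). Convolutions are evaluated as sums over
kernel offsets of shifted channel-mixing matrix products, which routes the
arithmetic through BLAS and keeps a forward pass of the scaled-down model
on a 32×48×32 volume well under a second.

Numerical details:

- Glorot-uniform weight initialization, seeded; identical (config, seed)
  pairs rebuild bitwise-identical parameters.
- Batch norm: momentum 0.99, ε = 1e-3. With batch size one, batch
  statistics make the layer behave as instance normalization; inference
  defaults to the same per-volume statistics (`bn_inference="batch"`),
  because running averages accumulated from single-volume batches are
  unreliable at short desk-scale runs. Running statistics are tracked and
  can be selected (`"running"`).
- Max-pool gradients route to the first maximum of each 2×2×2 window;
  argmax ties at the classifier resolve to the lowest class index. Both
  deterministic.
- Inputs whose extents are not divisible by 2⁴ raise by default; optional
  symmetric zero-padding (output cropped back) is available. The reference
  geometry (112×192×144) is exactly divisible.

## Training and cross-validation

Cost: `w_ce·CE + w_dice·(1 − mean soft Dice)` with w_ce = w_dice = 0.5.
CE is sparse categorical cross-entropy (voxel mean of −log p at the true
class, probabilities clipped at 1e-7); the Dice term averages the smoothed
soft Dice `(2Σp·y + s)/(Σp + Σy + s)`, s = 1e-6, over all four classes
*including background* — whereas the reported "average F1" convention
averages over the three tissues only. Both conventions are explicit,
named operations.

ADAM (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7), one volume per step, records in
a fixed order. After each epoch the mean cost over the training records is
re-measured in deterministic evaluation mode (dropout off); the weights of
the lowest-cost epoch are restored at the end, so re-evaluating the
returned model reproduces the best history entry. No validation split is
used for checkpointing by default (a holdout option exists but is off),
no data augmentation, no learning-rate schedule. The reference protocol
profile is 1000 epochs; desk-scale runs use far fewer.

Leave-one-out cross-validation holds each record out once. Per fold, the
standard scale is rebuilt from the training records only, the model is
re-initialized with seed = base seed + the held-out record's stable index
(its rank among sorted record ids), and training records are visited in
id-sorted order — so per-record results are invariant to the order records
are passed in.

## The phantom generator

The generator emulates the statistical structure the method assumes, at
configurable size (default 32×48×32 for desk runs, up to the full
112×192×144):

- **Geometry.** Nested regions of a perturbed ellipsoid (WM core r < 0.61,
  GM ribbon to 0.61·3^⅓ ≈ 0.88, CSF shell to 1.0, in brain-radius units;
  brain semi-axes 0.42 of each extent). The boundary ripple is a low-order
  angular harmonic, multiplicative in radius, so region-volume ratios are
  preserved and the GM:WM voxel count stays ≈ 2:1 — matching the roughly
  2× GM/WM imbalance of real infant records. Ripple phases are drawn per
  record.
- **Intensities.** Gaussian noise (σ = 0.06, arbitrary units) around
  per-tissue means. The GM–WM mean gap is `gm_wm_separation`·σ with
  default 0.5 — the isointense regime — while CSF sits > 3σ from the
  parenchyma, dark on T1 (0.30 vs center 0.65) and bright on T2 (0.90 vs
  center 0.45): the easiest tissue, as in real data. These are synthetic
  emulation values, not measured tissue parameters.
- **Record jitter.** One global affine intensity change per record and
  modality (scale U(0.7, 1.3), offset U(0, 0.15)) applied to the brain —
  what the standardization step must undo.
- **Voids.** A fraction (default 2%) of in-brain voxels is masked invalid
  and zeroed, uniformly at random.

What the phantom does **not** emulate: MR physics (no bias fields, no
Rician noise — noise is Gaussian), cortical folding, partial-volume
voxels, registration error. Passing tests therefore demonstrate the
pipeline's mechanics, determinism and learning ability on
intensity-plus-geometry structure; they do not certify accuracy on real
infant MRI, which is why the published cohort results are checked only via
the aggregation arithmetic on the published per-record values, not
re-measured.

## Problem sizes in the test and acceptance runs

Desk-scale profiles keep every run on one CPU: the scaled-down
architecture (filters 16/8/4/2, 2 input channels) trains on one 32×48×32
easy-regime phantom for 100 epochs (~2 min) and is expected to exceed 0.90
mean tissue Dice on its training volume; cross-validation plumbing uses
16×16×16 cohorts with 1–2 epoch stubs; the full-geometry forward pass for
shape verification runs at reduced filter counts (8/4/2/2). The full
65/32/16/8 configuration at 112×192×144 with 1000 epochs matches the
reference protocol but is a GPU-scale computation and is not exercised by
the tests.

## Known limitations

- No GPU path; the numpy implementation is single-threaded except for
  BLAS-backed products, so full-scale training is impractical here.
- Only NIfTI-1 and Analyze 7.5 I/O; no DICOM, no resampling or
  registration (inputs are assumed co-registered, as in the reference
  dataset).
- Batch size is fixed at one volume; batch norm is therefore effectively
  instance norm, and results with `bn_inference="running"` depend on run
  length.
- The void filler assumes voids are sporadic; a volume that is mostly void
  will be filled from a thin rim and carry little information.
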