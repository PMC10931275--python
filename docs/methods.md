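# Methods

## Problem and model

High-resolution peripheral quantitative CT (HR-pQCT) images extremities at
~61 µm isotropic voxels; patient motion during the ~2 min acquisition
smears the reconstructed volume and corrupts downstream bone-morphometry
measurements. Operators grade each acquisition stack on a five-level
ordinal visual scale (grade 1 = no visible artifacts … grade 5 = severe
artifacts), but manual grading is slow and only fair-to-moderately
reproducible between observers.

`motiongrade` automates this grading with a compact 3D convolutional
classifier. The core modeling assumption is that motion corruption is well
approximated by convolution of the ideal volume with an anisotropic 3D
Gaussian kernel: short, roughly linear patient movements integrate the
signal along the motion path, which to first order is Gaussian smearing
elongated along the motion direction. This assumption is what makes
synthetic pre-training possible — clean volumes can be degraded *with known
severity* to produce unlimited exactly-labeled training data.

## Degradation model

A motion kernel is parameterized by a severity level `L ∈ {1..5}`:

- level 1: identity (no degradation, exactly);
- levels 2–5: `σ_major` drawn uniformly from strictly ordered bands
  (in voxels): `U(0.5,1)`, `U(1,2)`, `U(2,3.5)`, `U(3.5,6)`;
- `σ_minor = σ_major / 4` on the two perpendicular axes, giving the
  elongated, streak-like appearance of real motion artifacts;
- orientation drawn uniformly from SO(3) (QR decomposition of a Gaussian
  matrix with sign correction), so artifacts are randomly oriented in all
  three dimensions.

The kernel is discretized analytically: the rotated covariance
`Σ = R·diag(σ²)·Rᵀ` is evaluated on an odd grid of side
`odd(ceil(6 σ_major))` and normalized to sum to 1. No kernel-grid
interpolation is involved. When the nominal support exceeds the smallest
volume dimension (severe levels on thin stacks), the support is clamped to
the largest odd value that fits and renormalized; the truncation removes
only far-tail mass. Convolution uses edge replication at the boundary
(implemented as edge-padding + FFT convolution in double precision), which
avoids dark halo rims that a zero boundary would introduce as a learnable
shortcut.

The σ bands are a declared convention of this package: the five-level
visual scale is qualitative and no numeric severity values exist to adopt.
The bands share endpoints, so severity is continuous across the scale —
draws near a shared boundary are intrinsically ambiguous, which keeps the
synthetic task honest rather than trivially separable.

## Synthetic phantom

Because no scanner data ships with the package, a generator produces
scaphoid-like phantoms: an ellipsoid filling 80% of the field, a cortical
shell (default 2 voxels — deliberately thin, as carpal bones have thinner
cortices than the radius or tibia), and a trabecular interior modeled as
Gaussian-smoothed white noise (correlation length 4 voxels) thresholded at
the quantile giving a 30% solid fraction, a standard porous-medium
surrogate. Marrow/bone intensity contrast is 0.15 vs 1.0 in arbitrary
units, plus additive Gaussian read-out noise (sd 0.03) applied before
degradation — so the smearing also shapes the noise spectrum, as in a real
scanner where motion corrupts the reconstruction including its noise.

What the phantom does *not* emulate: realistic carpal anatomy (shape,
cortical porosity), beam hardening, ring artifacts, or sinogram-domain
motion (double contours, streak interference). Passing the synthetic
benchmark therefore demonstrates that the pipeline can learn to rank and
classify Gaussian-smear severity from volumetric texture — not that the
trained weights transfer to scanner data. For real deployments the
fine-tuning stage must see observer-graded scans.

## Architecture

Four valid (unpadded) 3D convolution stages with 16/32/64/125 channels
(kernels 3³, 3³, 2³, 2³), ReLU activations, 2×2×2 max pools after stages 2
and 3, a global average pool, then fully connected layers of 50/25/5 units
with 12.5% dropout between them; the final 5-unit layer is
sigmoid-activated, one independent score per quality grade. The predicted
grade is the argmax, ties broken toward the lower (better-quality) grade —
deterministic, and conservative in the sense of not flagging a repeat scan
unless strictly warranted.

With the default configuration this realizes 102,582 trainable parameters.
Global pooling makes the count independent of input shape; a literal
flatten variant (`global_pool_before_head=False`) exists but inflates the
head far beyond that budget, which is why pooling is the default.

The stack is implemented directly in NumPy (im2col patch extraction +
BLAS matrix products, channels-last layout, float32), with analytic
backward passes verified against finite differences in the test suite.
The network is small enough that single-core CPU training is practical at
the benchmark sizes below.

The first convolutional layer is initialized as a bank of oriented
first/second directional derivative filters under a Gaussian envelope
(plus a low-pass filter and small symmetry-breaking noise), each scaled
to the expected norm of fan-in random init. Trained graders converge to
edge and boundary detectors in their first layer anyway; seeding that
representation saves scarce CPU update steps. Plain random init remains
available (`conv1_init="random"`).

## Training

Five independent sigmoid outputs are trained with per-unit binary
cross-entropy against one-hot targets (a softmax would contradict the
independence of the outputs). Optimizer: Adam, base learning rate 2e-3
with cosine decay to 5% over the run, batch size 4. These were chosen
because the CPU budget allows only a few hundred updates; a constant
1e-3 rate (`lr_schedule="constant"`) converges noticeably slower at equal
epochs. Epoch defaults: 4 pre-training + 6 fine-tuning. Each epoch
re-applies a fresh mirror/rotation symmetry per sample — the grade is
invariant under these, so it is free data diversity.

After the backprop phase, the fully connected head alone is refit to
convergence (default 300 epochs) on cached global-average-pool trunk
features. Backprop through the convolutional trunk dominates step cost,
so the main loop learns well-*ranked* features long before the five
output scores are calibrated against each other (high ROC-AUC, poor
argmax accuracy); head-only refinement costs seconds and fixes exactly
that. Inference averages the five scores over 8 mirror/rotation views of
the input (`symmetry_views`), a deterministic variance reduction that is
valid for the same invariance reason.

Two phases:

1. **Pre-training** on a balanced corpus built from clean (grade 1–2)
   volumes: each sample is randomly augmented (mirrors and 90° rotations —
   only shape-preserving group elements for non-cubic volumes), then
   degraded at a level drawn for it; the label is the level itself.
2. **Transfer learning**: the pre-trained weights initialize training on
   the target labeled set (synthetic levels on phantoms here; observer
   consensus grades on real data). With zero fine-tune epochs the weights
   pass through bit-identical, which the tests pin down as the
   initialization contract.

Consensus labels are the median of an odd number of observer grades
(median of an even count is ambiguous on an ordinal scale and is
rejected). Splitting is 80/20 and grouped by subject by default: patients
contribute several follow-up scans, and an ungrouped split would leak a
patient's anatomy across the train/test boundary.

Determinism: all randomness flows from explicit seeds (phantom seeds,
kernel draws, batch order, dropout masks, weight init); on a fixed
machine with single-threaded BLAS a run is exactly reproducible.

## Evaluation

The confusion matrix is reported as counts and row-normalized
percentages (rows with zero support are flagged rather than divided).
Accuracy is the trace over the total. ROC-AUC, specificity and precision
are macro-averaged one-vs-rest: per class the sigmoid score (AUC) or the
confusion-derived TN/(TN+FP) and TP/(TP+FP) are computed against all other
classes and averaged unweighted, excluding zero-support classes. Macro
one-vs-rest is the least-assumption reduction for a single headline number
on a 5-class problem and is recorded in every report. Stack grading
follows the most-severe rule: a stack's grade is the maximum grade within
it, and a scan's grade the maximum over its stacks.

## Benchmark sizes and numerical choices

The end-to-end synthetic benchmark uses 400 phantoms of 24×48×48 voxels
(24 axial slices of 48×48), 80 per level, grouped 80/20 split, 64
pre-training samples per level drawn from the clean training volumes.
These sizes keep a full run in the tens of minutes on one CPU core while
leaving 80 held-out volumes for evaluation. The transfer-learning
comparison runs at half size (200 phantoms of 16×24×24, three paired
seeds) for the same reason.

Other numerical choices:

- intensity normalization: percentile clip at (0.5, 99.5) then affine
  rescale to [0,1]; constant volumes map to zero rather than dividing by a
  degenerate range. Robust to the rare very-bright voxels of mineralized
  tissue.
- inference on volumes whose shape differs from the configured input:
  center-crop / zero-pad per axis (global pooling tolerates modest
  variation; padding keeps behavior defined).
- max-pool gradients are split equally among tied maxima, keeping the
  gradient sum exact.
- missing spacing metadata falls back to 60.7 µm isotropic with a warning
  (phantoms and test fixtures need not carry physical units).

## Known limitations

- The Gaussian-smear model ignores sinogram-domain motion effects
  (double contours, interleaved streaks); a network trained only on it
  will underestimate severity for such artifacts.
- The phantom is geometrically crude; results on it bound nothing about
  clinical data (see above).
- Adjacent severity bands share endpoints, so a few held-out volumes per
  run sit near a boundary and are intrinsically hard; perfect accuracy is
  not expected even in the synthetic setting.
- The hardest boundary by far is level 1 vs level 2: a level-2 kernel is
  a one-dimensional sub-voxel blur (`σ_major ∈ (0.5,1)`, minor axes
  ~0.2 voxels). For draws in the lower half of that band the anisotropy
  signal is smaller than per-phantom fluctuations of directional edge
  statistics — reference estimators built on directional spectral
  features also reach only ~80–85% on that two-class subproblem at these
  noise settings. Held-out benchmark errors are correspondingly dominated
  by level-2 volumes graded 1.
- Training is CPU-bound NumPy; it is deliberately sized for hundreds, not
  millions, of updates. The architecture, not the training engine, is the
  point.
- Scanco AIM volumes are not read directly; convert to NIfTI or TIFF
  upstream.
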