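# Methods

## Problem setting

Dental cone-beam CT (CBCT) trades dose for image quality: cone-beam
geometry and the absence of post-patient collimation admit scatter, which
shows up as metal streak artifacts, ring artifacts, noise and low-frequency
"cupping" shading, on an intensity scale that is not calibrated to
Hounsfield units.  Multidetector CT (MDCT) of the same anatomy provides a
high-quality reference.  `compunet` learns a mapping from degraded CBCT
volumes to MDCT-quality volumes from *paired but imperfectly aligned*
scans, using three ideas that tolerate residual misalignment:

1. **2.5D slicing** — each network input is a stack of three consecutive
   slices (N−1, N, N+1) and the output is the corrected central slice, so
   through-plane context is available without 3D convolution.
2. **Multi-planar averaging** — three independent single-planar networks
   are trained on axial, coronal and sagittal slicings; at inference the
   three reassembled volumes are averaged voxelwise.  Streaks that are hard
   to separate from anatomy in one plane are conspicuous in the other two.
3. **Contextual loss** — the training objective adds to the L1 pixel loss a
   feature-*set* similarity term that matches each target feature to its
   best-matching predicted feature, so a few pixels of spatial misalignment
   between input and target do not masquerade as intensity error.

## Synthetic study conditions

Clinical paired CBCT/MDCT data cannot be redistributed, so the package
ships a generator of paired phantom volumes that reproduces the
*statistical structure* the method assumes, and every quantitative claim
in the test suite is made on these volumes.

The clean (MDCT-like) phantom is a head-sized soft-tissue ellipsoid with a
mandibular arc (cortical shell at 1200 HU around a trabecular core at
300 HU carrying band-passed texture, amplitude 150 HU, correlation length
1.5 mm) and ten teeth rendered as concentric enamel (2000 HU) / dentin
(1600 HU) / pulp (80 HU) cylinders along the arc; two teeth carry metal
restorations (3000 HU).  Default grid: 64³ voxels at 1 mm isotropic.

The degraded (CBCT-like) counterpart adds, in order: radial sinusoidal
streak fans emanating from metal centroids in every axial slice containing
metal (amplitude 200 HU, 12-fold angular frequency, 20 mm radial decay);
concentric ring modulation about the axial rotation axis (25 HU, 3 mm
period); white Gaussian noise (σ = 40 HU); a radially varying cupping
shade depressing the centre by 100 HU; a global intensity transform
v → 0.75·v − 120 taking the volume off the HU scale; and finally a small
rigid misalignment resampled trilinearly with edge padding, emulating the
posture difference between scanners.  Streaks are simulated in the image
domain, not by forward projection: no claim of physical accuracy is made,
and none of the downstream machinery depends on one.  Artifact magnitudes
are free parameters of the generator; the defaults above were fixed once
as plausible desk-scale values.  Per-pair RNG streams are split by
artifact type, so toggling one artifact never changes another's
realisation.

What the generator does **not** emulate: beam-hardening spectra, scatter
physics, anatomical variability between patients (all pairs share the same
parametric anatomy up to axial pose), motion artifacts, and truncated
fields of view.  Passing tests therefore demonstrate that the pipeline's
machinery behaves as specified under controlled degradations — not
clinical performance.

## Preparation pipeline

For each pair: (1) the CBCT background is masked by median filtering
(radius 2 voxels), Otsu thresholding, largest-connected-component
selection and hole filling; (2) a monotone linear intensity map from CBCT
to MDCT HU is fitted by least squares through 256 paired quantiles inside
the mask and applied (the quantile pairing makes the fit robust to the
misalignment that still exists at this stage); (3) both volumes are
clipped to [−1200, 3071] HU; (4) the CBCT is registered to the MDCT by
maximising Mattes-style mutual information — a joint histogram with
32×32 bins and partial-volume (linear) binning, computed over the overlap
region — with a derivative-free coordinate pattern search (steps halved
when a sweep stalls; translations searched before rotations) on a 3-level
Gaussian pyramid, rigid stage (6 parameters) then affine stage (+3
log-scales, +3 shears); (5) the moving volume's bounding box is mapped
into the fixed frame and intersected to give the half-open overlap cuboid;
metrics and training use only voxels inside it.

Because the phantom's evenly spaced teeth make the MI surface
quasi-periodic in axial rotation, the coarsest pyramid level precedes the
local search with an exhaustive rotation grid scan (±15° in 5° steps per
axis) after a translation-only search; this removes the rotation local
maxima a greedy search cannot escape.  Registration recovers random rigid
perturbations up to 8 voxels / 10° to within 0.5 voxel and 1° in ≥ 9 of 10
trials.  Deformable fine-tuning is deliberately out of scope: the 2.5D
input and the contextual loss are the mechanisms that absorb what
rigid+affine leaves behind.

Conventions: arrays are (z, y, x), 0-based; cuboids half-open;
world = index · spacing + origin (mm); transforms map moving → fixed
points about an explicit centre.

## Network

Each single-planar network is a U-Net with a 4-block residual encoder
(two 3×3 convolutions per block with identity skip; stride-2 convolutions
between scales), a bottleneck, and a 4-block decoder with additive
attention gates on the skip connections: skip features x^l and the
upsampled coarser-scale gating signal g are projected to a common width,
passed through ReLU, projected to one channel and squashed by a sigmoid
into per-pixel coefficients α ∈ (0, 1); the gated skip is α ⊙ x^l.  The
output head is residual — the network predicts a correction added to the
central input slice — which speeds convergence for a restoration task
whose output is close to its input.  Inputs are normalised from the HU
clip window to [0, 1]; volumes store float32 and the normalisation is
computed in float64, making slice → reassemble round trips bit-exact.
Slice sizes not divisible by 16 are symmetrically zero-padded and cropped
back.  Encoder weights are randomly initialised (He); externally trained
encoder weights can be injected through the checkpoint mechanism but are
never required.  The three plane models are trained independently; the
paper-scale width is configurable and the desk preset uses base width 8.

The numerical core is an in-package reverse-mode autodiff on NumPy arrays
(`compunet.ndl`) providing exactly the primitives used here, verified
against finite differences.  Networks run in float32; Adam moments are
kept in float64.  Everything is seeded and single-threaded-deterministic.

## Loss

For predicted features {p_i} and target features {t_j} of one slice
(extracted per layer, mean-centred per set, L2-normalised):

    d_ij  = 1 − cos(p_i, t_j)
    d̃_ij  = d_ij / (min_k d_ik + ε)
    w_ij  = exp((1 − d̃_ij) / h)
    CX_ij = w_ij / Σ_k w_ik
    CX    = −log( (1/Np) Σ_j max_i CX_ij )

and the training objective is  L = mean|pred − target| + λ · mean_layers CX.
Defaults: λ = 0.1, h = 0.5, ε = 1e−5, following the conventions of the
contextual-loss literature; all are config-exposed, and λ = 0 recovers the
plain L1 models of the ablation.  The default extractor is a *seeded,
fixed* random convolutional bank (three stride-2 stages of 8/16/24
channels, ReLU) so the package needs no downloaded weights; raw 3×3
patches are available as an alternative, and an externally supplied
extractor can be passed in.  Feature sets larger than `max_features` are
subsampled uniformly without replacement (seeded); the library default cap
is 4096, the desk preset uses 256.

A property of the formula worth knowing: exactly duplicated features are
*discounted* — m identical features contribute 1, not m, to the matched
score — so CX(img, img) is positive for images with large exactly-constant
regions (e.g. pure air background).  This is intrinsic to the
ε-normalised formulation, is reproduced by the brute-force oracle in the
tests, and never binds on real or noisy synthetic slices, whose features
are distinct.

## Training

Adam, learning rate 0.001, batch 8, 100 epochs at paper scale.  Per
sample, one randomly drawn augmentation — horizontal/vertical flips
(p = 0.5 each), rotation uniform in ±90° with reflection padding, random
crop (240² at paper scale) — is applied identically to the three input
channels and the target.  Slices whose target contains < 2% voxels above
−900 HU are excluded as air-only.  A 10% per-slice validation split is
held out and its L1 error logged per epoch.  The L1 and CX terms are
logged separately; with λ = 0 the CX column is identically zero.

Ablation configurations: **model1** = axial-only, L1 (the single plane is
taken to be axial, the native CBCT reconstruction plane); **model2** = all
three planes, L1; **compunet** = all three planes, L1 + contextual.

**Desk-scale preset** (used by the test suite and the acceptance script;
these are the package's problem sizes, chosen once): 64³ volumes, crop 48,
base width 8, 5 epochs, 160 slices drawn per epoch from the pooled slices
of all training volumes (seeded), CX feature cap 256, validation capped at
16 slices.  The scaled-down ablation (15 training + 5 test pairs, 3
training seeds, streak-dominant artifacts) reproduces the qualitative
ordering: training loss decreases; the combined-loss multi-planar model
beats the degraded input on MAE; the multi-planar L1 model is no worse
than the single-planar one on NRMSE.

## Evaluation

Per volume, inside the overlap mask: MAE (HU); NRMSE = RMSE divided by the
reference volume's intensity range (normalising by the prediction's range
is available as an option — the two conventions coexist in the
literature); and the single-window (global moments) SSIM with k1 = 0.01,
k2 = 0.03 and dynamic range L = 4271 (the HU clip window).  Per-volume
values are aggregated as mean ± sd over test volumes.  Each metric is
tested against an independent brute-force transcription at 1e−10 on random
volumes.  The ablation table compares each configuration with the
degraded baseline by paired t-tests with Holm step-down correction at
α = 0.05 (identical samples are reported as p = 1); with the desk-scale
test-set sizes these p-values are descriptive, not powered.

## Numerical choices and degenerate inputs

- Otsu masking raises on constant volumes (threshold undefined).
- Intensity matching raises on empty masks or zero variance inside the
  mask; it is idempotent up to interpolation tolerance.
- MI binning uses each image's own min/max over the overlap, making the
  score exactly invariant to monotone linear rescaling; empty overlap is
  an explicit error, as is a disjoint field-of-view in the overlap cuboid.
- NRMSE raises when the normalising volume has zero range.
- Max/min autodiff subgradients split ties equally.
- Zero-amplitude degradation is the exact identity; all generated volumes
  are finite and clean phantoms stay within [−1200, 3071] HU.
- Training aborts with a diagnostic (plane, epoch, batch) on non-finite
  loss.

## Known limitations

- The synthetic anatomy is parametric; no claim about clinical images.
- Image-domain streaks lack beam-hardening physics.
- Registration assumes the ±15° coarse rotation scan brackets the true
  rotation; larger pose differences need a wider scan.
- The desk-scale preset trades accuracy for runtime; paper-scale settings
  (100 epochs, 240² crops, full slice pools) are configured but not
  exercised by the tests.
- Deformable registration and reader-study statistics are out of scope.
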