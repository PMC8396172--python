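# Methods

This note documents the models and procedures `murilung` implements, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic phantom does and does not establish.

## Image model and conventions

Volumes are scalar grids in Hounsfield units on isotropic lattices, indexed
`(z, y, x)` with `z` the cranio-caudal (rotation) axis. Voxel `(i, j, k)`
sits at `origin_mm + index · spacing_mm` (voxel centers); every physical
criterion (volumes in mm³, radii in mm) is computed from the spacing, never
from voxel counts, so the same rules apply at 63, 150, or 300 µm. The HU
rescale is `X_HU = 1000·((X − μ_air)/(μ_water − μ_air) − 1)`; the default
synthetic calibration is `μ_water = 0.02/mm, μ_air = 0`, which only fixes
the affine map — real calibrations are accepted via configuration. Mask
resampling interpolates trilinearly and re-binarizes at 0.5.

## Lung segmentation

Thresholding at −175 HU separates air + lung from soft tissue and bone.
A morphological closing then opening with a ball element (default radius
0.25 mm — larger than vessel cross-sections, smaller than the inter-lobe
gap; the radius is not dictated by the underlying method description)
makes the mask internally continuous. 26-connected regions are then
filtered by three rules: (1) no 26-adjacency to the background-air
component, defined as the 6-connected sub-threshold component touching the
volume border (this rejects the cradle air); (2) mean HU within the closed
interval [−600, −175] (air-only pockets fall below); (3) physical volume
within [200, 1200] mm³. When more than two regions survive, each region's
voxel coordinates are split by seeded 2-means (10 restarts; splits whose
smaller cluster holds under 25% of the voxels are treated as unimodal) and
the two regions with the largest center separation are kept — a merged
left+right lung region has two distinct centers of mass and outranks
compact debris. With one or two survivors, all are returned (left and right
lungs are legitimately separate components). Zero survivors raise an
explicit "no lung found" error rather than returning an empty mask.

## Tumor simulation

**Templates.** The bank holds synthetic blobby masks — exact top-k
superlevel sets of sums of overlapping anisotropic Gaussians — rather than
copies of segmented tumors, so the package carries no external data. Sizes,
intensity mean/std, and count (default 7) are configurable.

**Augmentation.** Each draw applies a uniform SO(3) rotation, independent
shears in [−0.2, 0.2] per off-diagonal component, and an isotropic scale
chosen so the transformed volume matches a log-uniform law. The law is
parameterized by its median (0.65 mm³) and 90th percentile (10 mm³); the
implied log-uniform support is [0.021, 19.8] mm³, then clamped to the
configured range [0.03, 70] mm³ (clamping only relocates the bottom ~5% of
the mass, leaving median and q90 intact). Binarization after interpolation
is volume-preserving: the k highest-valued voxels of the interpolated field
are kept, with k matching the continuous transformed volume. A fixed 0.5
level set was measured to lose ~5% volume at every size on these blobby
masks, which would bias the size distribution the augmentation is supposed
to realize.

**Retexture and blending.** Transformed masks are filled with i.i.d.
Gaussian noise (default 30 ± 40 HU, configurable — real nodule HU
statistics vary with contrast agent) and lightly smoothed (σ = 0.5 voxel);
the pre-smoothing variance is inflated by the measured RMS gain of the
smoothing kernel so the *post*-smoothing std matches the target. The binary
mask is blurred with a Gaussian (default σ = 0.15 mm) into blend weights,
which removes seam artifacts at the tumor boundary.

**Placement.** Candidate centers are sampled with probability proportional
to 1/d, where d is the Euclidean distance transform of the *working* mask
(lungs minus already-placed tumors), clamped at half a voxel to avoid
infinite boundary weight. A position is accepted when at most 10% of the
tumor's voxels (fraction of binary voxels — the most literal reading) fall
outside the lung mask and no placed tumor is overlapped. Carving accepted
tumors out of the working mask creates fresh boundaries, reproducing the
clustering of real nodules.

**Projection-domain insertion.** The scene is imaged with a circular
cone-beam geometry (source orbit about z; defaults: 200 mm source-object,
400 mm source-detector, magnification-matched detector pitch, 180–360
views over 360°; distances affect only the cone angle and are
configuration). The forward projector computes Joseph-style line integrals
(trilinear sampling at half-voxel steps along each source-pixel ray);
reconstruction is FDK: cosine weighting, row-wise band-limited Ram-Lak
filtering (optional Hann window), and distance-weighted backprojection,
scaled by Δβ/2 for the full-circle orbit. Both operators are linear, so the
projection edit `p + A(tumor) − A(parenchyma)` is computed as a single
projection of the attenuation difference, which cancels exactly (to the
last bit) outside the tumor footprint. Outside the blend support both
volumes are air (−1000 HU ⇒ zero attenuation). A bilateral filter
(brute-force Gaussian space/range kernel, defaults σ_spatial = 0.2 mm,
σ_range = 60 HU) reproduces the denoising step of the real pipeline.

**Dataset assembly.** The default simulated corpus is 60 image/label sets,
two tumors each, with 13 sets flagged for validation; a manifest records
template ids, affines, centroids, volumes, and outside-mask fractions per
tumor. Final augmentation applies one uniform magnification in [0.9, 1.1]
jointly to image and labels, then crops to the lung bounding box padded by
30 voxels per side. A voxel-domain compositing path (`method="voxel"`)
assembles large datasets quickly and doubles as the oracle against which
the projection route is validated.

## Detector

The network is a V-Net-style encoder/decoder: stages of one to three 5×5×5
convolutions, each followed by batch normalization, PReLU, and 1% dropout,
with a residual connection around every stage (the input is channel-tiled
when widths differ, and in decoder stages the residual is the up-convolved
feature map). Downsampling is a 2×2×2 convolution with stride 2;
upsampling a 2×2×2 transposed convolution; encoder features re-enter the
decoder by concatenation; a 1×1×1 convolution and sigmoid give a per-voxel
probability. The full-scale configuration has five stages; channel widths
are exposed in `NetworkSpec` (the published parameter total
under-determines them, so the count is reported, not targeted), and the
tested desk profile is 2–3 stages on 32³ patches.

The layer library is a self-contained float32 numpy implementation with
hand-derived backward passes, verified against finite differences in the
test suite. Stride-1 convolutions are computed as zero-padded linear
correlations via FFT (transform size ≥ n + k − 1 per axis, so no circular
wrap reaches the retained window); the weight gradient reuses the cached
input spectrum as a cross-correlation at the kernel lags.

Training minimizes `1 − 2Σpt/(Σp² + Σt²)` (squared-sum soft Dice; the
squared denominator makes the gradient vanish at p = t, and the both-empty
case is defined as perfect agreement). The reported overlap metric itself
is the cardinality form `2|P∩T|/(|P|+|T|)`. The optimizer is Adam with
initial learning rate 0.01 and β₁ = 0.9 (the stated "momentum" mapped onto
Adam's first-moment coefficient, since Adam has no classical momentum
term), β₂ = 0.999, batch 3, decaying ×0.9 every 100 epochs; one "epoch" is
one optimizer step on freshly sampled patches, the natural unit for
patch-wise training. Patches (96³ at full scale) contain at least part of a
tumor with probability 0.8, intensities are divided by 1000 (inputs are
already on the absolute HU scale), and a left-right mirror — the symmetric
flip within the coronal plane for a supine mouse — is applied with
probability 0.5. Four strategies are provided: `sim_only` (one network on
all simulated data), `real_only` and `combined` (per-fold networks, the
latter adding the full simulated training set to each fold), and
`transfer` (per-fold retraining from the sim-only weights; the pretraining
consumes the random stream before fold assignment so transfer with zero
retraining epochs reproduces the sim-only weights exactly). K-fold splits
(default 5) are balanced partitions: every scan is tested exactly once.
Inference tiles the volume with stride-12 overlapping patches and averages
per-voxel across every covering patch, clamping edge patches to the volume.

## Evaluation

Post-processing zeroes probabilities outside the lung mask, binarizes at
the decision threshold, labels 26-connected components, and rejects
components under 0.15 mm³ (below the system's reliable imaging size).
A labeled tumor is detected on voxel overlap with any detection (direct
hit) or when any detection centroid lies within 1.5× its equivalent-sphere
radius `r = (3V/4π)^{1/3}` of its centroid (near hit); tumor centroids are
voxel-center means. Extra detections on an already-hit tumor add nothing; a
single detection overlapping two labels credits both and is no false
positive. Precision, recall, and detection Dice `2TP/(2TP+FP+FN)` (the
harmonic mean of P and R) summarize the counts. The threshold sweep
(default grid step 0.01 on [0, 1]) reports the P = R crossing with linear
interpolation between bracketing grid points; if no detection survives at
any threshold it falls back to the argmax-Dice threshold with a warning.
Because a detection task has no true negatives, the ROC-like curve uses a
*pseudo* false-positive rate FP(t)/max_t FP(t); its trapezoidal AUC (on the
monotone upper hull anchored at FPR 0 and 1) is not comparable to
conventional ROC AUCs and is labeled as such. Size-binned detection rates
use edges {0.15, 0.25, 0.5, 1, 5, ∞} mm³ by default; empty bins are
reported as undefined.

## What the phantom establishes — and what it does not

The thorax phantom emulates the HU structure the pipeline's *rules* depend
on: tissue-class values, two separated lung lobes of realistic total volume
(~600 mm³), vessel trees as nodule-like confounders, bone, border-connected
cradle air, and additive Gaussian noise (default σ = 20 HU). Geometry is
specified in millimetres, so phantoms at different spacings describe the
same animal. It does **not** model airway anatomy, lobe fissures, beam
hardening, scatter, respiratory motion, or contrast kinetics; passing tests
demonstrate the pipeline's internal correctness and self-consistency, not
animal-study detection rates. Likewise the toy detector profile
demonstrates that training, inference, and scoring compose correctly on
large high-contrast tumors — not that the small-nodule sensitivity of a
fully trained network is reproduced.

## Problem sizes used by the test suite

The suite runs projection physics at 64³ voxels / 180 views (chord-profile
and round-trip oracles), insertion fidelity on a 64×72×72 noise-free
phantom with 6–20 mm³ tumors — the changed-voxel overlap measure is
resolution-limited by the ramp-filter point spread (~1 voxel) plus the soft
blend shell, so it is meaningful only for tumors well above the PSF volume
— augmentation statistics over 10⁴ draws, 10³ placements, and toy training
with three seeds on seven 100×80×80 simulated scans. These sizes are the
package's supported desk-scale profile; the full-scale configuration (63 µm
input resampled to 100 µm, 96³ patches, 5 stages, 5000 epochs) is exposed
in the same interfaces.

## Known limitations

- The cone-beam projector samples rays at half-voxel steps; line integrals
  are accurate to ~2% against analytic chords, which bounds the fidelity of
  quantitative insertion near sharp edges.
- FDK is exact only in the mid-plane; far cone angles are approximate, as
  in any single-circle Feldkamp reconstruction.
- The numpy network trains desk-scale models only; there is no GPU path.
- DICOM support covers standard rescale slope/intercept series export and
  import; vendor-specific raw formats are out of scope.
- The pseudo-FPR ROC construction is an explicit substitute for an
  undefined quantity; compare AUCs only within this package.
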