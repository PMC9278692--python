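# Methods

This note records the models, numerical choices and known limitations of
`sctkit`. The package reproduces, at digital-phantom scale, the assessment
loop used to qualify CBCT-to-synthetic-CT translation for adaptive
radiotherapy: phantom simulation → unpaired translation → image/contour/HU
assessment → calibration → stand-in dosimetry → DVH and gamma comparison.

## Digital phantoms (`sctkit.phantom`)

A subject is a parametric abdominal phantom: an elliptic-cylinder body of
soft tissue (≈40 HU, 10 HU texture) in air (−1000 HU), with organs painted
as ellipsoid/cylinder/sphere primitives in listed order (later organs own
overlapping voxels, and the returned masks reflect that final ownership).
Per-voxel values are `mean + N(0, std)` with organ means and STDs set to
measured abdominal planning-CT statistics: aorta 40±4, spinal canal 22±6,
heart 36±2, bones 349±64, kidney 21±7, lungs −719±11, liver 54±3 HU. The
default grid is 40×64×64 voxels at 4×3.5×3.5 mm — deliberately desk-scale;
all geometry is specified in millimetres, so finer grids change only cost.
Voxel indices are 0-based in (z, y, x) order and `world = origin +
index·spacing`; every module shares this convention.

The CBCT degradation adds, inside the body only: a cupping bias that falls
from 0 at the body surface to −`cupping_hu` at the deepest point (scaled
distance transform, default 25 HU); per-organ HU shifts whose defaults are
the differences between the measured CBCT and CT organ means (heart +38,
lungs +119, liver −16, ...); a 2 mm FWHM blur; Gaussian noise (default
σ=12 HU); and randomly oriented streaks with a Gaussian ridge profile
(default 6 per volume, 60 HU amplitude, 2 mm width). The noise, streak and
cupping magnitudes are not reported quantities anywhere we know of; they
were fixed once so that the organ-mean drift dominates (as the measured
tables imply) while the image remains clearly artifacted. An optional
`fov_crop_z` blanks end slices to emulate the reduced CBCT field of view
(off by default).

Inter-fraction change regenerates the phantom with shifted organ centres
(exact, because the phantom is parametric), carves −1000 HU air-pocket
spheres, and applies a smooth random displacement field. The "deformed CT"
surrogate warps the daily phantom by a smooth random field normalized so
its maximum displacement equals the requested residual registration error
(7 mm by default, the scale of reported deformable-registration failures
around mobile abdominal anatomy). Per-subject and per-stage seeds derive
from one master seed through `numpy.random.SeedSequence` spawn keys, so
every stage is independently reproducible; cohorts split ~11:6 into
train/test.

What the phantoms do *not* emulate: projection-domain physics (scatter,
beam hardening), realistic organ shapes and tissue heterogeneity,
couch/fiducial structures, and motion blur. Passing tests therefore show
the *assessment machinery* behaves correctly and that translation learning
is possible under controlled artifact statistics — not clinical
performance.

## Translation model (`sctkit.model`, `sctkit.nn`)

Two fully convolutional generators (CBCT→CT, CT→CBCT) and two patch
discriminators are trained on unpaired axial patches. Generators encode
with strided convolutions, transform through 3 residual blocks, and decode
with transposed convolutions; the network output is *added* to its input,
so an untrained generator is exactly the identity — a natural prior for a
translation whose target is "the same anatomy with corrected HU", and the
reason inference on a clean CT is nearly free of distortion from the
start. Slices are windowed to [−1000, 3000] HU and scaled to [−1, 1]
(window endpoints map to ±1); training crops free air to a working size
before random patch sampling, which at clinical scale reproduces the
four-fold 256×256 augmentation of a 480×384 slice.

The objective is the five-term sum (weights 10/1/1/1/1): L1 cycle
consistency; least-squares adversarial loss; an edge-preservation loss
comparing finite-difference gradient magnitudes of input and output (row
and column differences averaged, so constant offsets are free); an
idempotency loss `mean |G(y) − y|` for `y` already in G's target domain;
and mean anisotropic total variation of the outputs (sum of absolute
neighbour differences over both in-plane axes, normalized by pixel count).

Everything runs on a small reverse-mode autodiff engine over NumPy
(`sctkit.nn`): im2col convolutions via BLAS matmuls, fused instance
normalization, zero-insertion transposed convolution. Float32 throughout
training; every primitive is validated against central finite differences
in the test suite.

**Desk-scale discriminator.** At clinical scale the artifact signatures
occupy a usable fraction of the dynamic range; on the full [−1000, 3000]
window at desk scale they are 0.3–6% of the normalized range, and a
conventional PatchGAN cannot lock onto them within a CPU-sized iteration
budget. The discriminator therefore applies a *fixed* (non-learned) front
end — 4×4 average pooling and an affine input transform
`gain·(x − offset)` with gain 16 and offset −0.75 (≈ the mean normalized
HU of an abdominal slice) — before a 3-layer stride-2 convolution stack.
Pooling suppresses per-voxel noise and widens the effective receptive
field to 60 of the 64 patch pixels, which is what the low-frequency
cupping and organ-bias signatures require; the gain rescales the domain
differences to order one. The output remains a patch-level score map and
the receptive field stays smaller than the training patch.

**Optimization.** Adam (β₁=0.5) with generator lr 2·10⁻³ and discriminator
lr 10⁻², alternating one discriminator and one generator update per batch
(fakes detached for the discriminator step); both domains are shuffled
independently each epoch with seeds derived from the config seed, so a fit
is bit-reproducible. Plain SGD is available via `TrainConfig(optimizer=
"sgd")` but does not reach a useful equilibrium in a desk-scale budget,
which is why the adaptive-moment variant is the default. Non-finite losses
abort with the failing epoch/iteration. Desk defaults (64×64 patches, 8
base filters, 25 epochs) differ from clinical scale (256×256, 50 epochs);
clinical scale remains reachable through the same config. Inference is
slice-wise at full slice size (padded to the stride multiple), denormalized
and clipped to the training window, with grid metadata preserved.

## Assessment metrics

*Image quality* (`sctkit.metrics`): SNR = 10·log₁₀(Σr²/Σ(r−t)²), RMSE,
MAE, computed inside the body mask by default because air voxels dominate
whole-grid sums; identical images report SNR = +inf (serialized
explicitly, never NaN). Checkerboard composites alternate n×n blocks per
slice, top-left from the first image, remainder folded into the last
block. Organ HU statistics report per-subject means/STDs and a
cross-subject variability defined as the **sum of per-subject variances**
(one of two readings of the conventional Σσ² column; documented here
because the alternative — a pooled STD — differs numerically).

*Contours* (`sctkit.contours`): surfaces are boundary voxels
(face-connectivity erosion difference) at voxel-centre world coordinates;
max-Hausdorff is the classic max of directed max–min distances, "mean"
mode is the symmetric mean surface distance (the quantity usually
tabulated for organ contours; whether such tables average directed or
slice-wise distances is rarely stated — 3D symmetric was chosen).
Subvoxel meshing is deliberately omitted: at ≈1–4 mm spacing the boundary-
voxel error is far below the 1–7 mm effects measured. HD95 is likewise out
of scope.

*Calibration* (`sctkit.calibration`): piecewise-linear interpolation
through measured (HU, relative ED) knots, clamped to the end knots outside
the table; knots reproduce exactly. The bundled OBI curve is the published
Catphan-504 half-fan measurement (7 rows including the clamped maximum
point, HU 6000 → ED 3.920); the bundled planning-CT curve is a documented
generic synthetic stand-in, since site CT curves are only ever shown
graphically. The mass-density column is carried for report parity but
unused by the dose engine.

## Stand-in dose engine (`sctkit.dose`)

This is explicitly **not** a clinical dose algorithm. The study logic only
needs a deterministic operator, smooth in the electron-density map, that
turns HU errors into dose errors; a divergent-beam exponential ray-trace
provides exactly that. Each beam deposits `weight·exp(−μ·d_rad)` inside a
divergent rectangular field (source at 1000 mm SAD, gantry angle in the
axial plane), where `d_rad` is the water-equivalent depth — the midpoint-
rule line integral of relative ED along the source→voxel ray at a step of
half the smallest voxel spacing with trilinear interpolation. An arc is N
equally spaced static beams (default 12; beam geometry beyond "partial
arcs" is unreported, so these are documented placeholders). μ defaults to
0.005 mm⁻¹, a 6 MV-like effective attenuation. The engine is linear in
beam weights, monotone in added radiological depth, and deterministic.
Plans are normalized so the mean PTV dose equals the prescription (50 Gy
in 5 fractions by default); "same monitor units on a different image" is
re-expressed by reusing the reference plan's scale factor. No scatter
kernel, buildup, MLC or absolute-Gy claims.

## DVH and gamma (`sctkit.dvh`)

Cumulative DVHs are the fraction of structure voxels with dose ≥ each bin
edge (nonincreasing by construction; V100 = fraction at or above the full
prescription). The gamma index follows the standard dose-difference /
distance-to-agreement minimization: for each reference voxel above the
low-dose threshold, the minimum over evaluated positions within a search
radius (3·Δd) of √(dist²/Δd² + ΔD²/ΔD_crit²), with the evaluated dose
trilinearly interpolated on a sub-grid of spacing Δd/3, capped at 2.
Normalization is **global** (maximum of the reference by default,
prescription optionally) — the formulation the criteria descend from;
local normalization is not offered. The search enumerates every sub-grid
offset sorted by distance, letting each voxel stop once the distance term
alone exceeds its current best — an exact shortcut, verified in the tests
against a per-voxel brute-force oracle to 10⁻⁶ on small grids. 2D gamma
restricts the search to one orthogonal plane through the isocenter.
Resampling between dose grids is trilinear; voxels outside the source
extent are marked invalid and excluded from both numerator and denominator
of the pass rate. Gamma histograms default to 256 bins over [0, cap],
percent-dose-difference histograms to 1024 bins with the same 10%
threshold. Iso-level contours are extracted per plane by marching squares;
contour divergence is the symmetric max–min point distance between two
level sets.

The pipeline computes gamma against the deformed-CT-based plan (the
clinical verification reference). Contours "drawn on" the synthetic image
are emulated by a 1 mm misalignment surrogate — slice-wise translation
cannot displace anatomy, so residual contour differences in practice come
from contouring variability; 1 mm matches the scale such studies report
for sCT contours, and was fixed a priori. The deformed-CT candidate
carries the dataset's 7 mm surrogate.

## Problem sizes

The shipped experiments run on one CPU: phantoms 40×64×64 at 4×3.5×3.5 mm;
training cohorts of 3 subjects (2 train / 1 test, 80 slices per domain),
30 epochs × 10 batches of 8 at 64×64, three seeds; dose grids equal to the
phantom grid with 12-beam arcs. These sizes were chosen as the smallest at
which every directional comparison (MAE ordering, contour ordering, PTV
dose deviation ordering, generator idempotency) is stable across seeds.

## Known limitations

- Phantom realism is deliberately minimal (primitive geometry, additive
  artifact model, no projection physics).
- The dose engine's numbers are stand-in quantities; only *differences
  between plans computed the same way* are meaningful.
- The exact formulas of the gradient/idempotent/TV losses in the source
  literature are supplementary material we re-derived from their stated
  purposes; each is isolated behind one function so alternates are
  swappable.
- The discriminator's fixed pooled/gain front end is a desk-scale device;
  at clinical scale and GPU budgets a conventional PatchGAN front end is
  expected to work and can be recovered with `pool=1, input_gain=1`.
- Whether clinical inference runs on full slices or reassembled patches is
  unstated in the source literature; full-slice inference was chosen (the
  generators are fully convolutional, so both are available).
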