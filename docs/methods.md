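# Methods

## The calibration model

`tpscolor` calibrates an image by warping its color space, not its
pixel grid. Each pixel's (R, G, B) triplet is a point in the cube
[0, 255]³; a chart photographed in the scene supplies N control pairs —
the measured patch color Pᵢ and its known reference color Vᵢ — and the
calibration is the unique thin-plate-spline interpolant f with
f(Pᵢ) = Vᵢ. The spline splits into an affine map (4×3 coefficient
matrix A, absorbing exposure, white-balance gains and linear channel
crosstalk) plus a radial-basis part (N×3 weights W on the kernel
U(r) = 2r²log(r + 1e-20), r the Euclidean distance in RGB) that bends
the space to absorb gamma and other smooth nonlinearities. The
coefficients come from one dense (N+4)×(N+4) linear solve; the four
zero rows appended to the right-hand side impose P_homᵀW = 0, the side
conditions that make the bending part orthogonal to the affine part.
Two structural facts follow and are tested: the fit reproduces its
controls exactly, and W ≡ 0 whenever the targets are an affine image of
the controls ("zero bending energy iff affine").

The kernel is the 2D biharmonic form evaluated on 3D distances. The
classical spline minimizing 3D bending energy would use U(r) = |r|;
we keep the 2r²log(r+ε) form deliberately — it is the form this
calibration approach is defined with, it remains a valid exact
interpolant, and the 1e-20 shift regularizes log(0) so U(0) = 0 without
a branch. The solve is plain LU factorization with no smoothing term:
the method is exact interpolation by design, and a smoothing variant is
out of scope.

### Numerical choices

- **Scale.** All spline math runs on the [0, 255] real scale, because
  every distance the field reports (ΔRGB) is in 8-bit units.
- **Conditioning.** On this scale kernel entries reach ~10⁶ while the
  homogeneous block is O(1), so cond(L) of a perfectly healthy system is
  ~10¹³–10¹⁴ (measured at N = 7, 24, 140). The fit refuses systems with
  cond(L) > 10¹⁶, which in practice flags near-duplicate measured
  colors; the condition number is recorded on the model for audit.
- **Duplicate controls.** After 8-bit quantization two patches can
  measure identical colors, which makes K exactly singular. Exactly
  coincident rows are merged before fitting, with their reference
  targets averaged and a warning logged; exact duplicates that survive
  to assembly raise an error naming the patch ids.
- **Gamut.** `warp` itself never clips — values can leave [0, 255] —
  and the pipeline clips only at 8-bit export, rounding half away from
  zero. In-gamut colors are therefore preserved exactly; out-of-gamut
  warp results saturate rather than being rescaled.
- **Reproducibility.** Fitting is deterministic (no randomness), and
  whole-image evaluation streams through fixed 4096-pixel blocks. The
  block size is an internal constant, so evaluating an image whole,
  in tiles, or pixel-stream-chunked produces bit-identical output and
  memory stays flat on large (e.g. 4000×3000) images.

## Reference construction

When a chart's reference colors are not supplied directly, they are
computed from per-patch spectral reflectance measured on the 400–700 nm
grid at 10 nm steps (the grid portable integrating-sphere instruments
report). The chain is illuminant-weighted summation against the CIE
1931 2° observer (perfect diffuser normalized to Y = 100), Bradford
chromatic adaptation from the measurement illuminant (D50 for the
instruments this emulates; D65 supported) to the nominal D65 white,
the standard XYZ→linear-sRGB matrix, sRGB companding, and scaling to
[0, 255] with clipping. Adaptation targets the *nominal* D65 white
point rather than the table-derived one so that a flat unit spectrum
maps to (255, 255, 255) exactly and flat grey spectra stay neutral to
well under 1/255 per channel. Off-grid spectra are linearly resampled
(and the resampling logged) rather than rejected, since instruments
vary. Reference values are stored as reals on [0, 255].

The shipped 24-patch chart uses the widely published nominal sRGB
values of the classic 24-patch ColorChecker. The shipped 7- and
140-patch charts are synthetic fixtures with the *structure* of their
physical counterparts (primaries + neutrals; a dense cube sampling plus
skin tones and a grey ramp) but invented values; real charts should be
measured and loaded from CSV.

## PLS baseline

The comparator is a chemometric-style regression: measured RGB is
expanded to polynomial features (degree 2 with cross terms by default,
9 predictors), centered, and regressed onto reference RGB by PLS2.
The NIPALS fit is delegated to scikit-learn's `PLSRegression` (with a
tightened convergence tolerance) behind the `PLSCalibrator` surface;
the test suite checks it against an independent SVD-of-cross-covariance
oracle. Component count (default 6) is reduced automatically, with a
logged warning, when the expanded predictors are rank-deficient. The
defaults are configuration, not claims: the baseline exists to give the
spline something honest to beat.

## Synthetic scenes

No photographs ship with the package; the generator stands in for the
acquisition experiment (two cameras × four light conditions × three
chart sizes). A `DistortionSpec` applies, in fixed order:

1. per-channel gains (illuminant cast; the tungsten preset uses
   (1.25, 1.0, 0.75), neon pushes green, sun is near-neutral);
2. a 3×3 near-identity mixing matrix (sensor crosstalk; one matrix per
   synthetic camera);
3. optional exposure normalization — the linear stage is rescaled so no
   color in the cube can saturate, emulating an operator metering
   exposure off the chart's white patch; the presets enable it, because
   saturation destroys information no calibration can recover and a
   deliberately exposed photograph avoids it;
4. per-channel gamma on the [0, 1] scale (tone response, one value per
   camera in the presets);
5. optional additive Gaussian noise (8-bit scale) and 8-bit
   quantization, both seeded.

`render_checker` tiles the distorted patches into an image with
1-pixel neutral gutters and returns the layout and ground truth
alongside. Replicate studies draw random distortions from the same
family: gains U[0.75, 1.3], gammas U[0.85, 1.2], row-normalized
crosstalk with off-diagonals U[0, 0.06], exposure-normalized. Holdout
colors are sampled uniformly over [10, 245]³ to stay clear of gamut
edges. All preset and family values are fixture choices meant to be
plausible in magnitude — they are not measurements of real hardware.

What the generator does *not* emulate: spatially varying illumination,
vignetting and lens falloff, chromatic aberration, demosaicing
artifacts, specular reflections on patches, and spectral (metameric)
effects — the distortion acts on tristimulus values, not spectra.
Passing the synthetic studies therefore shows the method recovers
smooth global color distortions of the kind cameras and lamps impose;
it does not certify performance under spatially non-uniform light,
which chart-based calibration cannot correct in principle.

## Evaluation metrics

ΔRGB is the Euclidean distance between two colors in sRGB, bounded by
255√3 ≈ 441.7. The within-distance averages ΔRGB-to-reference over the
N fitted patches; the holdout distance averages over the M patches (or
colors) kept out of the fit; the inter-distance takes, for each shared
holdout patch, the mean pairwise ΔRGB of its calibrated color across
acquisition conditions, then averages over patches — the reconciliation
of "difference among conditions" with a single mean over M, and the
two-condition case degenerates to the plain pairwise distance (unit
tested). The nearest-control association is the Spearman rank
correlation (average ranks on ties) between a holdout color's distance
to the nearest calibrated control color and its residual error, with a
t-approximation p-value, t = ρ√((n−2)/(1−ρ²)); for n ≤ 10 an exact
permutation p-value is used instead. A positive association is the
expected signature of an interpolation method: error grows with
distance from the control cloud. Heavier factorial analyses are out of
scope; the evaluation emits a tidy per-patch CSV so any stats package
can run them.

## Problem sizes and study design

The replicate studies used by the test suite and the acceptance script
are sized to make their directional claims stable: 100 random
distortions for the recovery and association studies, 50 for the
chart-size ordering, 116 holdout colors per scene, and chart sizes 7,
24 and 140. With noiseless distortions the 24-patch fit typically
leaves ~1.4 ΔRGB of holdout error (interpolation error between
controls), the 7-patch fit ~2.7, and the 140-patch fit ~0.24 — the
ordering that motivates mid-sized charts as the practical optimum.

## Known limitations

- The warp is only as good as the patch measurement: a mis-declared
  layout rectangle poisons a control point silently. Layouts are
  declared by hand (JSON); automatic chart detection is out of scope.
- Exact interpolation means measurement noise in the patches is
  reproduced faithfully rather than averaged away; with very noisy
  patches a smoothing spline would generalize better, but that variant
  is deliberately not implemented.
- Colors far outside the control cloud's convex hull are extrapolated
  by the affine part plus decaying kernel influence; errors there can
  be large (the Spearman association quantifies exactly this effect).
- One warp is valid for one acquisition setup (camera + settings +
  illumination); models are serialized to JSON precisely so they can be
  reused across images of the same session, and no further.
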