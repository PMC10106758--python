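# Methods

This note documents the models, parameter choices and numerical
conventions behind `flowradiomics`, and what the synthetic phantom does and
does not establish about real 4D PC-MRI data.

## Analytic flow phantom

The phantom is a rigid tube (radius default 12 mm, centerline length
120 mm, straight or semicircular arch) carrying one of eight closed-form
cross-sectional velocity profiles:

| profile | velocity field (local tube frame) |
| --- | --- |
| poiseuille | axial `v_p (1 − (r/R)²)` |
| plug | axial `v_p` |
| helical | Poiseuille axial + solid-body azimuthal `Ω r` (Ω default 8 rad/s) |
| central_jet | axial Gaussian, width `R/3` |
| displaced_jet | Gaussian offset by `f·R` along the first in-plane axis (f default 0.4) |
| angulated_jet | central Gaussian tilted by `β` off-axis (default 25°) |
| multi_jet | three Gaussians (width `R/4`) at 120° spacing, offset `0.55 R` |
| vortex | azimuthal `0.9 v_p (r/R)` + weak parabolic axial carrier `0.3 v_p` |

Velocity is zero outside the lumen (`r > R`, membership decided at voxel
centres) and scaled per timeframe by a waveform. The default waveform is a
raised-cosine systolic pulse over the first 40 % of the cycle with a 5 %
diastolic tail; its maximum is exactly 1 so `peak_velocity` is the true
peak. The axial-plus-azimuthal profiles are divergence-free in the
continuum; discretized divergence vanishes on interior voxels and is only
non-zero at the lumen wall, which the tests account for by eroding the
mask. The Gaussian jets are kinematic templates of post-stenotic jets, not
Navier–Stokes solutions; no claim of physical consistency is made for
them.

The scanner model applies, in order: linear resampling of the waveform to
the scanner's temporal resolution (20–38 frames/cycle is the realistic
range), a multiplicative velocity bias, and additive zero-mean Gaussian
noise with standard deviation `noise_sigma_fraction × VENC` per component
(VENC default 150 cm/s). Phase wrapping, background phase offsets and
k-space effects are deliberately out of scope — the pipeline assumes
preprocessed velocity data. The observer model perturbs a 2D ROI by a
smooth random radial displacement (low-order angular Fourier modes, peak
amplitude `contour_jitter_mm`, default 1 mm) plus a uniform
dilation/erosion bias, always keeping a single connected region.

Cohorts draw radius `N(12, 1.5²) mm`, age uniform in range, sex Bernoulli,
and disease-dependent profile mixtures and peak velocities: no valve
disease uses laminar profiles (Poiseuille/plug/helical) at
`N(1.0, 0.15²) m/s`, aortic stenosis uses jet/vortex profiles at
`N(3.2, 0.5²) m/s`, matching the clinical picture of post-stenotic jets at
3–4 m/s. This gives well over 2 s.d. of separation by construction; the
classification benchmark therefore demonstrates *pipeline recovery of a
separable signal*, not expected clinical performance.

## Geometry and resampling

Planes sit on the centerline with the normal equal to the local tangent
(increasing arc length). In-plane axes are reproducible: the first axis is
the normalized projection of a fixed global reference vector (x̂, falling
back to ŷ, ẑ when near-parallel to the normal) and the second is
`normal × first`. Twelve planes by default: the four landmarks plus five
equidistant intermediates between A1.1 and B1 and three between B4.1 and
D1.1; the per-segment split is configurable since only the total of twelve
is normative.

MPR resampling uses trilinear interpolation at a 1 mm cell-centred grid
(default extent 48 mm); pixels outside the source grid are flagged invalid
and excluded from every mask, never extrapolated. Trilinear interpolation
is exact for fields multilinear in the coordinates, which the tests
exploit as an oracle. All coordinates are physical millimetres, voxel
indices 0-based.

ROI propagation across timeframes is rigid centroid tracking: the mask is
translated by the integer-pixel shift of the through-plane-speed centroid
inside a search window (reference mask dilated by 6 mm). This replaces
deformable (morphon-style) registration, which is external machinery the
phantom does not need — its ROI motion is translational by construction.
Area is preserved exactly; zero-flow frames fall back to the untranslated
mask with a warning.

## Parameter maps

Vorticity is computed on the 3D source grid with spacing-aware central
differences (one-sided at borders) and then resampled to the plane;
in-plane 2D differences cannot recover all curl components. Spacings are
converted to metres so vorticity carries 1/s.

Degenerate pixels never produce NaN: speeds below 1e-6 m/s give WPD 0,
angle 90°, LNH 0, each with a low-signal flag. The helicity map is signed
by default (the sign encodes handedness; an absolute-value option exists).
The vorticity map destined for radiomics is the through-plane component
self-normalized by the per-plane per-timeframe maximum of |ω·n| over the
ROI, which maps it into [−1, 1]; a fixed reference in 1/s is available as
an alternative when cross-plane comparability of vorticity magnitudes
matters more than per-plane contrast.

Normalization is affine with clipping: throughflow [−6, 6] m/s →
[−2048, 2047]; angle [0, 180]° and WPD [0, 1] → [0, 4096]; LNH and
normalized vorticity [−1, 1] → [−2048, 2047]. Values stay floating point;
integer quantization happens only at gray-level discretization so bin
boundaries are controlled in one place.

## Radiomics features

Discretization follows the fixed-bin-width convention, bin width 25
normalized units anchored at the ROI minimum:
`level = floor((v − min)/25) + 1`. Texture families are computed in 2D:

* GLCM — distance 1, the four unique directions, symmetrized; features
  computed per direction then averaged. Degenerate conventions:
  correlation of a zero-variance marginal is 1; information-correlation
  denominators of 0 give 0.
* GLRLM — run matrices of the four directions summed before features; the
  run-percentage denominator is `4 × N_pixels`.
* GLSZM — zones are 8-connected components of equal level.
* GLDM — dependence is the count of 8-neighbours equal to the centre
  (tolerance α = 0); the matrix is indexed by (level, dependence + 1).
* NGTDM — per-pixel difference from the mean of valid 8-neighbours;
  a zero coarseness denominator returns the documented constant 1e6.

The full six families define 93 features (18 + 24 + 16 + 16 + 14 + 5). The
default catalogue drops 14 redundant or derived variants — first-order
TotalEnergy and Range; GLCM SumAverage, SumSquares, MCC, Imc1, Idmn; the
normalized non-uniformity duplicates in GLRLM/GLSZM/GLDM; and the GLDM
gray-level emphases that repeat their GLRLM counterparts — leaving 79 per
map. With 16 shape features the signature is 5 × 79 + 16 = 411 values per
plane per timeframe; these counts are enforced as invariants of the
default catalogue, which is itself configurable and serializable.

The 16 shape descriptors extend the classical 2D set with motion terms:
pixel and mesh (shoelace) area, Crofton perimeter (an intercept-count
estimator that is unbiased for smooth contours, unlike staircase polyline
length), perimeter-to-area ratio, maximum diameter over boundary-pixel
corners, major/minor axis lengths from second moments, elongation,
eccentricity, circularity, compactness, extent, solidity, equivalent
diameter, and — relative to the reference timeframe — centroid drift and
fractional area change.

Every texture feature is verified in the test suite against independent
brute-force oracles (pair enumeration, run scanning, flood fill, neighbour
counting) written without shared code, on ≥ 20 random small maps at 1e-8
absolute tolerance.

## Reproducibility statistics

Feature curves use the normalized cycle fraction, not absolute
milliseconds, since heart rates differ between acquisitions; lower-rate
curves are linearly upsampled to the finest grid before comparison. The
ICC model is two-way random effects, absolute agreement, single rating
(scanners/observers are exchangeable raters); the two-way mixed
consistency variant is selectable. Rating units pool planes and timeframes
(one unit per subject × plane × timeframe). A zero-variance rating matrix
is defined as ICC 1 with a degeneracy flag. Category boundaries: 0.5 and
0.75 belong to the higher category, 0.9 to good. Selection takes the
intersection of features at least moderate in both the inter-scanner and
inter-observer tables, in deterministic (sorted) order. Confidence
intervals for ICCs are out of scope.

## Classification

The classifier is L2-penalized logistic regression (C default 1) on
z-scored features at the peak-systolic frame (maximum volume flow rate,
ties to the earlier frame) of plane A1.1, positive class aortic stenosis.
Because no held-out protocol is canonical here, both stratified 5-fold
cross-validation (the default headline) and resubstitution are computed
and labeled; reported numbers always name their protocol. Feature
importance is the absolute standardized coefficient with name-ordered
ties.

## Problem sizes and determinism

The shipped benchmark uses two cohorts of 30 subjects on a 2 mm source
grid with 20 timeframes and 2 % VENC noise; the reproducibility
experiments in the tests use 4–6 subjects, 2 scanner replicates and 4
frames on a single plane. These sizes were chosen so the full suite
exercises every stage end to end at desk scale while the statistical
checks (noise calibration, binomial sex-ratio bounds, ICC monotonicity)
retain adequate power. All randomness flows through explicit
`numpy.random.default_rng` seeds; every operation is bit-reproducible for
fixed inputs, and the CLI embeds the configuration hash and seed in every
artifact.

## Known limitations

* The phantom's jets are kinematic, not dynamic; wall shear stress and
  flow-displacement measures are out of scope.
* Inter-observer variation is modelled purely as contour perturbation;
  real observers also differ in plane placement, which is not simulated.
* Passing the synthetic benchmark shows the pipeline recovers constructed
  effects; it does not estimate accuracy or ICC distributions on clinical
  data.
* Centerline extraction and vessel segmentation are upstream of this
  package; a centerline with the four landmarks must be supplied.
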