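# Methods

`exmkit` quantifies calibrated expansion microscopy (ExM) of endosomes: how
faithfully a hydrogel-expanded sample preserves nanoscale geometry, what the
true (intrinsic) expansion factor is, and what the spatial statistics of
endosomal markers look like once images carry physical, biological-scale
coordinates. Every analysis is exercisable against synthetic scenes with
exact ground truth; this note records the models, the defaults and why, and
the limits of what the synthetic benchmarks demonstrate.

## Coordinate and image model

All arrays are ordered `(z, y, x)`; all physical quantities are nanometres.
Voxel centers sit at `(i + 0.5) * voxel_size`, indices are 0-based, and the
frame is right-handed. `ImageVolume` couples the intensity grid to per-axis
voxel sizes; a volume without a known voxel size cannot be loaded (no silent
1 nm default). The PSF is a separable anisotropic Gaussian with
`FWHM = 2 sqrt(2 ln 2) sigma`, one lateral and one axial sigma.

## Synthetic scenes (`fixtures`)

The generator emulates the structures the real assays see:

- **Compartments** — ellipsoidal shells of membrane puncta. Angular
  clustering uses von Mises–Fisher draws around `n_clusters` random axes
  (defaults: 12 clusters, concentration 30), reproducing nanocluster shell
  texture without committing to a biological clustering model. Nanocluster
  size and count per endosome are not well constrained by published
  measurements, so these are free parameters and documented as such.
  Interior puncta are uniform in the enclosed volume.
- **Nanocages** — point sources with true diameters drawn from a normal
  distribution (default mean 28.3 nm, SD 1.6 nm, matching purified-particle
  TEM measurements); never blurred at generation time.
- **Distortion** — a global isotropic expansion factor followed by local
  radial Gaussian bumps `u(p) = a * exp(-|p-c|^2 / (2 f^2)) * (p-c)`;
  negative amplitude models under-expansion of small compartments. The bump
  is smooth and invertible for |a| < 1 (rejected otherwise); ground truth
  displacement at any generated point equals the stored pre/post offset
  exactly.
- **Rendering** — separable Gaussian splats on a ±4 sigma patch; with
  normalization on, an interior unit source integrates to 1 within 1%.
  Detector noise is Poisson on gain-scaled intensities followed by additive
  Gaussian noise; both optional so zero-noise tests stay exact.
- **TEM-like images** — each nanocage is an annulus whose *outer* diameter
  is the cage's true diameter (negative stain outlines the particle
  boundary, which is what manual ellipse tracing measures), with ring
  thickness 6 nm, one-pixel anti-aliased edges and mild area-preserving
  ellipticity jitter. Cages are placed on a jittered grid so no two overlap
  — manual analysis measures isolated, fully visible cages.

Everything is deterministic given the integer seed.

What the fixtures do **not** emulate: continuous membrane staining (puncta
are points, not filament/sheet textures), intraluminal vesicles or tubules,
depth-dependent aberration, detector-array (Airyscan) correlated noise, and
gel-mechanical coupling between neighboring structures. Tests passing on
these scenes validate the estimators' numerics, not their behavior on every
real-image pathology.

## Registration (`registration`)

Pre/post volumes are related by a similarity transform (isotropic scale +
rotation + translation). The family is deliberate: anything anisotropic
would absorb the distortion signal that the flow stage is supposed to
measure. Estimation: rescale the pre volume by the known macroscopic
expansion factor, phase-correlate for a global shift, then iterate block
matching — normalized cross-correlation of 32³ blocks (stride 16, search ±8
voxels, correlation cutoff 0.3, up to 5 iterations, 0.5 nm convergence
tolerance), parabolic sub-voxel peak refinement, and a weighted Umeyama
similarity fit with one round of 2.5×MAD outlier rejection. Flat blocks are
excluded; fewer than 4 surviving correspondences is an error. The iteration
stops (and reverts) if the residual RMS would increase, so the diagnostic
residual series is non-increasing by construction. On synthetic 4× and 9.4×
expansions the recovered scale is within ~0.15%.

## Distortion mapping (`distortion`)

The dense 2D flow engine implements polynomial-expansion optical flow
(quadratic local signal model fitted under a Gaussian window; per-pixel
linear constraint on displacement solved in a Gaussian-weighted
neighborhood; coarse-to-fine pyramid with warping). Defaults: 3 pyramid
levels, 15 px averaging window, 5 iterations per level, expansion window
half-size 7 px (sigma 1.5). For the volumetric endosome benchmark we use 2
levels and a 21 px window — displacements there are 1–2 px so a deep
pyramid adds nothing, and the wider window suits sparse point texture; both
are exposed in `FlowParams`.

Registered volumes are resectioned into every x–y and x–z plane; each plane
yields two components, and the fused vector is
`(dz, dy, mean(dx_xy, dx_xz))`. Pixels without signal in either image
(below an Otsu-type floor, with a quantile fallback for very sparse planes)
are masked. An optional normalized-convolution smoothing of the fused field
(`smooth_sigma_nm`, e.g. 60 nm ≈ the expansion-neighborhood scale)
stabilizes pointwise readouts such as map extrema against the heavy-tailed
per-voxel flow noise; distortion features of interest are much broader, so
the attenuation is a few percent.

Known limitation: at a contracting shell *boundary*, a 2D section reads the
apparent in-plane ring shrinkage `(R/rho) dR`, which exceeds the true
in-plane projection `(rho/R) dR` of the 3D motion near section-tangent
regions. This is intrinsic to resectioned-flow fusion; the radial map can
overstate under-expansion by up to ~1.5× right at a small compartment's
membrane, while volumetric texture away from boundaries is recovered within
a few percent (verified against analytically warped volumes).

Error-versus-length-scale uses the pair-differential definition: for each
scale `L`, sample valid voxel pairs with actual separation in
`[0.9 L, 1.1 L]`, take `e = |u(p) - u(q)|`, report
`RMSE(L) = sqrt(mean e^2)` and `percent = 100 RMSE / L` on the post-ExM
physical scale. Pair differences are invariant to residual uniform shift
(registration residue is not distortion); the raw-magnitude variant is kept
behind `raw_magnitude=True` for comparison. Scales that collect fewer than
10 valid pairs are flagged NaN, never fabricated.

## Calibration (`calibration`)

- **TEM widths** — automatic path: Otsu threshold, connected components,
  hole filling, second-moment ellipse with axes `4 sqrt(lambda)` (a ±2σ
  extent equals the full boundary of a filled uniform ellipse); width is
  `(major + minor)/2`, the same rule as manual ellipse tracing. The
  correspondence between this estimator and manual tracing is approximate
  by design; on rendered populations the mean is recovered well within the
  sampling error of the truth.
- **Fluorescence spots** — difference-of-Gaussians detection at a stated
  scale, local maxima above `median + 5 * 1.4826 * MAD`, per-spot 2D
  Gaussian fit on the in-focus plane (patch ~1.25× the detection FWHM).
  Acceptance: R² ≥ 0.8 and width within [0.5×, 3×] the detection scale —
  deliberately loose because genuine post-ExM width distributions are broad;
  rejected spots are flagged and counted, never silently dropped, with a
  moment-based fallback width.
- **Expansion factors** — macroscopic EF is the mean of per-dimension
  post/pre gel-size ratios. Intrinsic EF divides the mean accepted spot
  width by the reference nanocage diameter; its SD comes from the
  spot-width SD by the delta method, and per-spot EFs are emitted so either
  per-cell or per-gel aggregation can be formed downstream (which the
  original analyses used is not stated). The raw-width definition folds PSF
  broadening into the EF on purpose — that is how the calibration is
  defined; a quadrature PSF correction exists behind a flag and warns that
  it changes EF values.
- **PSF metrology** — bead stacks are centroid-aligned with cubic
  interpolation (linear shifting measurably broadens profiles), averaged,
  and Gaussian-fitted along each axis; off-center beads are rejected with a
  count, and a bead larger than the measured FWHM flags the result.
  `effective_psf` is simply FWHM / EF.
- `calibrate_scale` divides voxel sizes by the EF, touches no intensities,
  records provenance, and is exactly invertible.

## Surface tracing (`surface`)

The limiting membrane is reconstructed from membrane-marker puncta by an
iterated, averaged triangulation: intensity-weighted centroid; per iteration
a random 70% subsample's convex hull is intersected with rays along a fixed
icosphere direction set (level 3, 1280 faces, by default); per-direction
radii are averaged over 25 iterations, smoothed by 2 neighbor-averaging
passes in radius space (which preserves the star shape exactly and is
area-neutral on a sphere), and meshed on the icosphere. Hull facets are
chords and sag inside the true boundary (~1.4% in radius for ~350-point
subsamples of a sphere); since the puncta are unbiased samples of the
membrane, the radial field is rescaled so the surface passes through their
mean radial position (`chord_correction`, on by default). Sphere area and
volume are then recovered within ~1.5%.

Preconditions: at least 12 puncta, and a star-shape test (every icosphere
direction must have a punctum within 60°) — failing clouds need a manual
centroid or denser labeling. The radial parameterization cannot represent
concave topologies; tubules, invaginations and intraluminal vesicles are
out of scope by construction.

Projection: puncta within a ±band (default 40 nm) of the mesh are assigned
to their nearest face by exact point-triangle distance (ties resolve to the
lowest face index); each projected punctum covers a disk footprint of half
its width, and a face counts as occupied when its incenter lies inside any
footprint (Euclidean proxy for geodesic distance; resolution is set by the
icosphere level). Occupancy is a face-area percentage, monotone under added
puncta. Puncta beyond the band (e.g. luminal cargo) are listed separately,
and the band is per-call so different markers can use different bands.

## Puncta statistics (`punctastats`)

Segmentation runs on calibrated volumes so all filters are physical:
rolling-ball-style background subtraction (grayscale opening, 200 nm ball),
Gaussian smoothing at the seed scale, seeds above a MAD floor (with an Otsu
fallback when the background is empty or the MAD mask floods), seeded
watershed, and a [min, max] nm³ volume filter. Punctum width is the mean
in-plane FWHM-equivalent extent on the brightest z-plane (2D, matching
ellipse-fitting practice; the axial extent is separate). Low-solidity
regions are flagged as probable merges — a documented failure mode, not an
error.

The moment-preserving threshold solves the Tsai construction on the
8-bit-quantized histogram: the closed-form below-threshold fraction `p0`
from the first three gray-level moments, then the 8-bit level whose
cumulative histogram best matches `p0` (the reported value represents the
cut strictly between quantized levels). Manders percentages use these masks
per channel, are directional (`|A∩B|/|A|`), exactly recomputable from the
stored counts, and an empty mask yields an undefined (not zero) direction.
Masks are built in 3D by default; the per-plane variant is a flag, since
stack-wise usage of the original plugin is ambiguous. Chord tables
normalize marker occupancies into arc fractions and require every ordered
pair. Hypothesis testing is not reimplemented — tidy tables are the
interface to external statistics tools.

## Problem sizes

The bundled benchmarks use 64³–128³ voxel grids, 20–50 nm voxels, hundreds
to ~2500 puncta, 138 nanocages, and 60 rendered spots — sizes at which every
estimator's error is dominated by method, not sample noise, and the whole
suite completes in a few minutes on one CPU. All stochastic steps take
explicit integer seeds.
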