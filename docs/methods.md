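# Methods

This note documents the models, conventions and numerical choices behind
`osgrad3d`, in the order the pipeline runs them, followed by the phantom
generator that stands in for real scans and the known limitations.

## Geometry conventions

Volumes are `(z, y, x)` arrays with isotropic voxels; a voxel's physical
center is `(index + 0.5) · voxel_size_um`. Anisotropic containers are
rejected outright rather than resampled, because every downstream distance
statement assumes one edge length. Grayscale data are widened to float on
read; raw integers are never modified in place.

## Registration

The pre- and post-stain scans of the same aggregate differ by a rigid
motion plus a possible global scale (scanner geometry), and — by
construction — in intensity, which is the signal of interest. Intensity
metrics are therefore avoided entirely: the similarity transform is
estimated in closed form from paired landmarks (least squares via SVD of
the cross-covariance, with the reflection guard), and the fit is exactly
invariant to landmark re-ordering and to a common rigid motion of both
sets. The residual RMS is reported per coordinate, so it is directly
comparable to the landmark digitization noise; with 20 landmarks and 1 µm
noise it sits near 1 µm, and parameter error shrinks as landmarks are
added. At least 4 well-spread landmarks are recommended; fewer than 3 or a
collinear set is an error.

Resampling uses trilinear interpolation — monotone, so no overshoot can
leak into the subtraction — and marks voxels mapped from outside the
moving volume in a validity mask (NaN fill by default). All downstream
statistics ignore invalid voxels.

## Os mapping

Both scans are rescaled by the affine map sending the mean gray value of a
plastic-holder ROI to 40 and of a quartz ROI to 120. The mean (not the
median) keeps the calibration linear, which makes normalization exactly
idempotent. ROI coordinates are shared between the two scans of a
registered pair. `Os_CT` is the median-filtered difference post − pre;
radius 1 (3×3×3) is the default kernel, the smallest isotropic choice.
Where NaNs are present the filter takes the median of the valid neighbors
only (a shifted-stack `nanmedian`), so masked voxels do not poison their
neighborhood. Negative Os_CT values are kept: they carry the noise
information that the extent rule needs. Reference-material summaries apply
one pass of Tukey fences (1.5 × IQR) before reporting percentiles; the
rule is recorded in the table metadata.

## Material segmentation

Features per voxel: for σ ∈ {0.3, 0.7, 1.0} voxels, the Gaussian-smoothed
value, the gradient magnitude and the Laplacian of the smoothed field —
nine features. Derivatives are central differences of the smoothed field
rather than sampled Gaussian-derivative kernels: at σ < 1 voxel the
sampled kernels are so truncated that a constant image produces a large
spurious response, while finite differences are exactly zero there. σ is
in voxel units and configurable.

The voxel classifier is a 100-tree random forest with √n_features
subsetting and a fixed seed (the protocol prescribes forest parameters
only for the object-level classifier, so these are package defaults).
Training samples come from a sparse scribble volume (0 = unlabeled,
1–4 = pore, POM, matrix, dense) — a file-based replacement for interactive
painting. Prediction is restricted to an aggregate mask obtained by Otsu
thresholding of the smoothed pre-stain volume, largest component,
morphological closing (radius 4 — the closing must exceed the radius of
pore mouths at the surface, or boundary-connected pores fall outside the
mask), and hole filling. The majority filter counts votes per class over
the 3×3×3 neighborhood with out-of-mask voxels contributing nothing; ties
break toward the smaller class code, and a class absent from the
neighborhood can never be introduced. Exterior is imposed last and exactly
complements the mask.

Segmentation runs on the normalized pre-stain volume only. Adding the
Os_CT map as a feature channel would mix the measurement into the
segmentation that conditions it, so it is deliberately not done.

## POM morphology

POM components use 26-connectivity (fibrous strands at 5 µm resolution
frequently touch only diagonally); the size filter is strict:
`voxel_count > 5000` (6.25×10⁵ µm³ at 5 µm voxels). Sub-threshold
components stay POM voxels for volume accounting but are not analyzed as
objects.

Shape descriptors are the package's operationalization of the standard
morphometric traits:

- Second central moments of the voxel centers, plus the moment of the unit
  cube (I/12) so a single voxel has the moments of a cube rather than a
  point. Semi-axes `a ≥ b ≥ c` follow from `λ = axis²/5`; elongation =
  a/b, plateness = b/c. The cube term keeps `c > 0` even for 1-voxel-wide
  lines, so plateness stays finite for any non-empty mask (degenerate
  masks report large but meaningful ratios instead of a sentinel).
- Compactness = sphericity `36πV²/S³`, with the surface area from a
  marching-cubes mesh. Face counting would under-rate a digital sphere's
  sphericity by roughly half; the mesh estimator puts it near 0.8, the
  practical maximum for a voxelized ball.
- Mean Os_CT and mean pore distance over the object's voxels.

Descriptors are invariant to translation, axis permutation and (for the
ratios) uniform scaling.

The fibrous/compact classifier is a 500-tree random forest trying 2
variables per split, trained on manually labeled objects (CSV of id,
class) with a ~70/30 train/validation split (default fraction 324/463) and
reporting validation accuracy plus the out-of-bag error.

## Distance gradients

Distance maps are exact Euclidean distance transforms scaled to µm; the
reference phase is at distance 0 and exterior voxels are NaN. Connected
pores are the pore components containing at least one voxel 26-adjacent to
exterior. The air-filled variant keeps connected pores whose local
thickness (largest-inscribed-sphere diameter, computed by descending over
EDT radii and painting spheres; radii discretized at voxel resolution)
reaches the drainage diameter — default 30 µm. This
threshold-plus-connectivity rule is a deliberately simplified capillary
model, not a water-retention simulation.

Profiles bin Os_CT by distance (default bin = 1 voxel = 5 µm) over a
restricted class. The bin populations partition the restricted voxels, so
the voxel-weighted mean of bin means equals the class mean to full
precision. The restriction excludes non-exterior voxels within the median
filter radius of the exterior (`interior_core`): their filter window
crosses into air and drags the difference map low, a measurable bias of a
few tenths of an Os_CT unit concentrated at large pore distances. Across
aggregates, one profile per aggregate is averaged and the standard error
uses n = number of aggregates, not voxels.

"Bulk soil" is operationalized as restricted-class voxels beyond the 75th
percentile of the distance distribution (flag, recorded in outputs). The
extent is the center of the first bin whose mean lies inside
`bulk mean ± 1 SD` and stays inside for 3 consecutive bins; persistence 1
reproduces the plain single-crossing rule and is selectable. Empty bins
cannot veto persistence. A profile that never enters the band is censored
at the maximum distance and flagged. Direction is depletion when the
near-reference profile sits below the band, enrichment above. The
affected volume fraction is the share of restricted voxels closer than the
extent. Because the detector returns the first bin *center* fully inside
the band, the detected extent sits systematically within one bin above the
continuous crossing point — the resolution limit of the rule, verified
against phantoms with closed-form crossings.

## Accounting

Per class: volume fraction of non-exterior voxels, mean Os_CT, and their
product ("Os amount"), which sum exactly to the whole-aggregate mean. The
matrix amount is the MAOM proxy; it is reported in arbitrary Os_CT units
and deliberately never converted to absolute carbon contents, since
mineral Os sorption makes matrix Os an imperfect MAOM measure. The fibrous
share uses only size-filtered, classified POM objects; with none present
it is reported as missing, never as 0. Cohort regressions are ordinary
least squares with Pearson R; laboratory covariates (TOC, fractionation
masses, …) are user-supplied columns and never fabricated.

## Phantom generator

The generator emulates the structures the protocol measures, with fully
known truth:

- A quasi-spherical aggregate (radius 0.38 × grid, smooth radial
  perturbation) in air; a plastic slab and quartz grains outside it as
  normalization anchors.
- Pores as infinite-cylinder biopores (guaranteed boundary-connected) and
  bounded planar cracks (a mix of connected and isolated), carved until
  the porosity target is met; the overshoot is below one object's volume,
  keeping generated porosity within ±20 % relative of the target.
- Compact POM as randomly oriented (super)ellipsoids with aspect ratios
  ≤ 2, placed at least 3 voxels from pores; fibrous POM as tortuous
  random-walk tubes seeded at pore walls. Objects never touch each other
  (placement retries with a dilation check), so connected-component
  analysis recovers exactly the placed objects.
- True Os field: POM objects carry per-object constant Os drawn from a
  lognormal (median 80, log-SD 0.5 — Os levels of individual POM pieces
  vary widely in practice); matrix Os =
  `matrix_os_mean · (1 − exp(−d_pore/λ_pore)) +
  amplitude · exp(−d_POM/λ_POM) + N(0, matrix_os_sd)`. Exponentials are
  monotone, single-length-scale shapes whose band-crossing extent is known
  in closed form — the property the extent tests exploit.
- Pre-stain grays: per-class levels (pore < POM < matrix < dense, with
  plastic and quartz distinct from all soil classes) plus Gaussian noise;
  the post-stain scan adds the Os field divided by the normalization gain,
  plus its own independent noise. Two-anchor normalization and subtraction
  therefore recover the truth field up to √2 × the per-scan noise.

Defaults (128³ grid, 5 µm voxels, 12 % porosity, 3+3 POM objects,
λ_pore = 30 µm, λ_POM = 20 µm, matrix Os 40 ± 2, noise SD 2) describe a
densely pored topsoil aggregate at the protocol's scan resolution. The
standalone shape bank (`generate_labeled_shapes`) uses gently bent Bézier
tubes (bend capped at 15 % of length, axis ≥ 5 diameters) and
superellipsoid blobs, each ≥ 5000 voxels, for classifier work.

What the phantom does **not** emulate: CT artifacts (beam hardening,
rings, partial-volume blur), textured or graded material interiors,
anisotropic fabric, or POM decay-stage continua. Passing the benchmarks
therefore demonstrates correctness of the measurement chain on geometry
and gradients of realistic scale — not robustness to scanner physics.

## Problem sizes and determinism

Unit tests run at 64³–96³; the headline benchmarks (segmentation, extent
recovery) at 128³, the protocol's native working scale for a single
aggregate section. All randomness flows from explicit seeds: the same seed
reproduces phantoms bit for bit, classifier fits exactly, and pipeline
tables byte for byte (the manifest records parameters, seeds, version and
checksums).

## Known limitations

- Only similarity registration; no deformable correction, so swelling
  during staining would register imperfectly.
- σ of the feature stack is in voxel units; at other scan resolutions the
  physical feature scales shift accordingly.
- The local-thickness estimator discretizes radii at voxel resolution;
  thickness is accurate to ~1 voxel diameter.
- The trait formulas for elongation/plateness/compactness are this
  package's inertia-ellipsoid definitions; other morphometry software
  normalizes differently, so absolute values are comparable only within
  this package.
- The bulk-soil definition (far-field quantile) and the persistence rule
  are parameterized conventions; both are recorded in every output.
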