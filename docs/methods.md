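# Methods

## The registration model

An integrated CLEM instrument shares one field of view between a
fluorescence camera (FM frame, pixels of ~100 nm) and a scanning electron
beam (EM frame, pixels of ~5 nm). To first order the two frames are
related by a similarity transform — isotropic scale `s`, rotation `θ`,
translation `(t_x, t_y)`:

    x^F = a·x^E − b·y^E + t_x,   y^F = b·x^E + a·y^E + t_y,
    a = s·cosθ,  b = s·sinθ.

The parameterization is linear in `(a, b, t_x, t_y)`, so the
least-squares fit on matched point pairs is closed-form: with centred
coordinates `x̃ = x^E − x̄^E`, `ũ = x^F − x̄^F`,

    a = Σ(x̃ũ + ỹṽ) / Σ(x̃² + ỹ²),   b = Σ(x̃ṽ − ỹũ) / Σ(x̃² + ỹ²),

and the translation maps the EM centroid onto the FM centroid. Two
non-coincident pairs give four equations for four unknowns — the unique,
zero-residual minimum of the problem — hence the two-pair minimum that
the fitter enforces. Reflections are unrepresentable (`s > 0` and the
`(a, b)` form has determinant `s² > 0`); a mirrored scene cannot occur
physically between the two arms of one instrument and would only surface
as large residuals.

What the similarity cannot absorb — field-dependent optical and scan
distortions of either microscope — appears in the residual difference
vectors

    δ_i = (x_i^F, y_i^F) − T(x_i^E, y_i^E),

which satisfy the usual least-squares identities when `T` is fitted on
the same pairs: `Σδ_i = 0` and zero projection on the scale and rotation
modes `(x, y)` and `(−y, x)`.

## Spot localization (radial symmetry)

CL pointers are circularly symmetric, so every intensity gradient points
through the center. The estimator builds gradients at the inter-pixel
midpoint lattice from the two diagonal finite differences (3×3
boxcar-smoothed), attaches to each midpoint the line along its gradient,
and returns the point minimizing the weighted sum of squared
perpendicular distances to all lines — a 2×2 linear solve, no iteration
and no initial guess. Weights are squared gradient magnitude divided by
distance to the gradient-weighted centroid (floored at half a pixel),
which suppresses far-field noise gradients. The patch median is
subtracted first so a constant background cannot bias anything.

Properties verified by the suite: exactness on centred symmetric spots,
< 0.02 px bias on off-centre noiseless Gaussians of FWHM ≥ 2.5 px,
equivariance under translation/rotation/transposition/flips, invariance
under intensity scaling, and RMS error within 10% of a shot-noise-
weighted nonlinear Gaussian fit (the near-maximum-likelihood reference)
on Poisson-noise spots. Note the *unweighted* Gaussian LSQ fit is about
10% worse than radial symmetry under Poisson noise, because it gives the
high-variance bright pixels full weight; the weighted fit is the honest
benchmark.

Detection (which pixels hold spots at all) is conventional: Gaussian
smoothing, local maxima above a robust background threshold
(median + 2·1.4826·MAD), ranked by intensity with ties broken toward the
smaller (row, col), output ordered by (y, x). The refinement patch radius
defaults to 1.5×FWHM but is clipped to 0.45× the median nearest-neighbour
detection spacing, so dense arrays (pitch down to ~1.4×FWHM) do not bleed
into neighbouring patches.

## Grid correspondence

One FM exposure records a whole pointer array, so detections arrive
unordered and must be matched one-to-one to the commanded beam grid.

*Initial guess:* the four extreme detections of the convex hull (greedy
farthest-point selection, valid for any rotation) are matched to the four
grid corners over the four cyclic assignments; the least-squares corner
misfit selects the assignment. For square grids all four assignments tie
by symmetry, so near-ties are broken toward the rotation closest to a
prior (default 0: the two arms of an integrated instrument are nearly
aligned by construction). This is a genuine ambiguity — without a prior,
a square array admits four indistinguishable labelings.

*Iterative pairing:* map the grid through the current transform, form
mutual-nearest-neighbour pairs (mutuality prevents two grid nodes from
claiming one detection), discard pairs with residual above
`min(max(3·median, 0.5 px), 0.5×mapped pitch)`, refit, repeat until the
pair index set repeats (max 20 iterations). The 0.5 px floor keeps
ordinary sub-pixel localization scatter from being discarded when the
median residual is tiny; the half-pitch cap guarantees no pair ever
crosses to a neighbouring node. Nearest-neighbour iteration on a lattice
has a finite rotation/scale basin (at ~10° initial rotation error the
outer nodes lock onto neighbouring spots in a self-consistent wrong
matching); if the loop stalls or converges with few pairs and a median
residual above 0.15× the pitch, a fresh edge-based initial guess is
derived from the detections themselves and the loop rerun, which makes
the outcome independent of the supplied initial transform.

## Distortion field

Averaging `δ_i` per grid node over repeated array exposures estimates the
distortion profile: the per-node mean (in nm), sample count and pooled
per-axis standard deviation. Nodes deviating from a 3×3 local-median
smoothed field by more than 5 standard errors *and* more than 5× the
robust spread of all such deviations are flagged anomalous but retained —
isolated deviant vectors are a real property of the camera pixel array,
not noise. Arbitrary FM positions are evaluated by bilinear interpolation
in lattice-index space (the lattice may be rotated in the FM frame);
outside the calibrated coverage the nearest node value is used with a
warning, or an error in strict mode — the field is never extrapolated.

Correction is a two-pass scheme: fit `T` on the raw pairs, evaluate the
field at each mapped position `T(em_i)`, subtract the interpolated vector
from the observed FM position, refit. One pass suffices: with ≤ 200 nm
distortion over a ≥ 50 µm field the second-order term is far below
localization noise.

The simulator's ground-truth field generator draws a random cubic
polynomial vector field on the calibration lattice, adds the requested
number of localized anomalies (~2× the smooth peak, random orientation),
projects the whole field orthogonal to the four similarity modes
*evaluated at the node positions*, and scales the smooth part's peak to
the requested magnitude (200 nm default). The projection matters: it is
what makes "distortion" well-defined as the part of the frame mismatch
that the linear registration cannot absorb. For recovery studies the
lattice should be placed on the mapped pointer grid (`grid_to_fm`
argument) — exactly where the physical calibration samples the field —
otherwise each per-array fit absorbs a similarity component of the field
and the node means are biased. The field is exactly linear in its
magnitude parameter, and a fixed seed gives bit-identical output.

## Overlay accuracy bootstrap

From a calibrated pool of pointer pairs, draw N distinct pairs (without
replacement within a draw, independently across draws), fit the
similarity, map the EM-image center into the FM frame; repeat (5000×
default) and report the spread of mapped centers. The scalarization is
the per-axis-equivalent radial standard deviation
`sqrt((sd_x² + sd_y²)/2)`; the full radial value `sqrt(sd_x² + sd_y²)`
is emitted alongside, so either convention can be read off. The fits are
evaluated vectorized in closed form for all draws at once.

With i.i.d. per-pointer jitter σ the accuracy is ≈ σ/√N: translation
noise contributes σ²/N, and the scale/rotation noise contributes through
the lever arm between the probed point and the drawn subset's centroid.
That second term scales as 1/N², so the measured log–log slope over
N ∈ {4 … 256} is ≈ −0.54 rather than exactly −0.50 — visible only at the
smallest N and fully reproduced by a fresh-noise Monte-Carlo oracle. At
12 nm jitter and N = 9 the accuracy is ~4.3 nm.

## The virtual microscope

The simulator emulates, with exact ground truth: FM exposures of pointer
arrays (isotropic Gaussians of 300 nm FWHM — the diffraction limit — on a
constant background, Poisson shot noise plus Gaussian read noise, the
standard camera model); EM images of 40 nm nanosphere fiducials
(anti-aliased uniform disks, deliberately low signal-to-background, as
for silica spheres under SEM) with their diffraction-limited FM
counterparts; a ground-truth similarity transform; and the distortion
field described above, applied in the FM frame:
`FM_observed = T(EM) + D(T(EM)) + noise`.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| FM pixel | 100 nm | 60×/0.95 NA objective on a ~6.5 µm camera pixel |
| EM pixel | 5 nm | typical SEM magnification for whole-field imaging |
| scale s | 0.05 | the pixel-size ratio |
| rotation | 2° | small residual camera/scan-axis misalignment |
| pointer FWHM | 300 nm | optical diffraction limit (low beam energy) |
| grid | 25×25, 4 µm pitch | dense calibration array, 625 pointers |
| spot amplitude / background / read noise | 1000 / 100 / 2 counts | gives ~2.5 nm single-spot localization error, consistent with nm-scale pointer localization; these are free parameters of the simulation, not measured instrument values |
| jitter σ (coordinate mode) | 12 nm | per-axis localization error consistent with sub-5 nm accuracy at N = 9 |

*Coordinate mode* (`simulate_pointer_pool`,
`simulate_fiducial_coordinates`) skips image rendering entirely and emits
localized coordinates with isotropic Gaussian jitter — used for
registration-statistics studies where rendering cost and localization
bias are irrelevant.

What the simulator does **not** model, and hence what passing tests do
not certify on real data: the physics of CL generation (electron
interaction volumes, substrate yield), non-Gaussian PSFs and optical
aberrations, stage drift during acquisition, spatially correlated camera
noise, asymmetric or clustered fiducials, and detection in crowded
fluorescent backgrounds. The statistical machinery (fit variance,
N^(−1/2) scaling, field averaging) transfers; absolute nanometre numbers
depend on instrument noise levels that must be measured, not assumed.

## Numerical choices and degenerate inputs

* Angles reported in (−π, π]; translations in FM px with nm alongside.
* Fit errors: < 2 pairs, all-coincident EM points, or an all-coincident
  FM cloud (zero scale) raise `ValueError` with the reason.
* Radial symmetry: patches below 5×5, constant patches, or a singular
  2×2 normal matrix (relative determinant < 1e−12) raise
  "no radial structure".
* Pairing keeps at minimum the single best mutual pair above the floor so
  a tight threshold cannot empty the pair set silently; fewer than 2
  survivors is an error quoting the two-pair minimum.
* Detection ties are broken toward the smaller (row, col) index;
  detections are emitted sorted by (y, x) — all stages are deterministic
  given the seed, and pipeline reruns are byte-identical.
* Overlay resampling inverts the corrected mapping to first order in the
  field (`em ≈ T⁻¹(p − D(p))`), exact to < 0.1 nm for 200 nm fields.
* Fiducial placement is rejection sampling with a retry bound; a packing
  request beyond the random-sequential-adsorption limit fails with an
  explicit error rather than looping forever.

## Problem sizes used in the shipped studies

The test suite and acceptance script run the method at the study scale a
desk reproduction warrants: 50 arrays × 625 pointers (31 250 pairs) for
the accuracy curve and distortion recovery, 1000–5000 bootstrap
resamples, 10 independent scenes for the fiducial cross-validation, and
≥ 100 patches for the localization-oracle comparison.

## Known limitations

* The corner-based initial guess needs the four extreme detections to be
  actual grid corners; heavy occlusion of corners (not just random 5%
  dropout) would require seeding the pairing from a user-supplied
  transform.
* The distortion field is defined on the calibration lattice's convex
  span; registrations of areas outside the calibrated field of view fall
  back to nearest-node values.
* `register_with_distortion` applies one correction pass; fields
  approaching the pointer pitch in magnitude would need iteration.
* Anomaly flagging is a diagnostic heuristic (local-median comparison);
  it is intentionally conservative and flags some nodes in steep smooth
  gradients at high signal-to-noise.
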