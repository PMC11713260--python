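# Methods

`doseaccum` reproduces, end to end and on fully synthetic data, the
workflow used to estimate the dose actually accumulated by pelvic
organs over a fractionated external-beam course when the anatomy of the
day is imaged with weekly cone-beam CT (CBCT): deformable registration
of the planning CT (pCT) to each CBCT, construction of an extended-FOV
"merged CBCT", two independent cumulative-dose pathways, spatial dose
summation to a reference week, and geometric (DSC/TRE) plus dosimetric
(DVH metrics, percent-difference bands, 3D gamma) evaluation.

Because no clinical images are distributed, everything is exercised on
a digital pelvis phantom whose weekly deformations are closed-form
diffeomorphisms.  That gives every downstream stage an exact ground
truth: the true displacement field, true weekly contours, and true
landmark positions.

## The phantom

The planning CT is a painted voxel model: an elliptic-cylinder body,
a two-layer bony ring (cortical shell, trabecular interior), bladder
(ellipsoid, volume-targeted), rectum (cylinder), an uterus/cervix
target, and fat/muscle background.  Default tissue HU are taken from a
published example-patient ROI table (bladder 11.4, muscle 46.9, fat
−97.9, trabecular 143.1, cortical 851.0 HU); rectum contents (25 HU)
and target (55 HU) are design choices inside the soft-tissue range.
The default bladder volume is 89 cc, the first patient of the cohort
volume table; weekly target volumes span 0.65–1.8× to emulate a clinic
without a bladder-filling protocol.

### Weekly deformation model

Week *i*'s anatomy is `phi(x) = c + rho(r) (x−c)/r + t` where `c` is
the bladder centroid, `t` a rigid setup shift (a few mm), and
`rho(r) = r (1 + (lam−1) exp(−r²/2σ²))` a radial stretch with Gaussian
falloff (σ = 50 mm by default).  `lam` is solved by quadrature +
root-finding so the warped bladder hits the requested *volume* ratio.
The map is diffeomorphic for `lam` below ≈3.24 (checked; stronger
requests raise).  The pull-back field `u(y) = phi⁻¹(y) − y` is the
ground-truth DVF; `phi⁻¹` is obtained by Newton inversion of the
monotone radial profile to ~1e-10 mm.  Gas pockets are painted into
the deformed image (intensity only) for selected weeks.

### CBCT acquisition model

Degradation is deliberately image-domain, not projection-physics:
a linear contrast scale (default 0.9), a radial quadratic shading field
(±25 HU), additive Gaussian noise (15 HU SD), and field-of-view
truncation to a 465 mm diameter × 160 mm cylinder padded with −1000 HU.
The FOV transverse figure is configurable because published FOV numbers
for this scanner class conflict (46.5 cm diameter vs ±8.75 cm from
isocenter); we default to the former.  What a green test establishes is
therefore robustness to *linear* intensity distortion, stationary
noise, smooth shading, and truncation — not to scatter, beam hardening,
lag, or motion artifacts.

All weekly volumes live on the planning-CT grid (the rigid shift is
part of the voxel content).  This makes the merged-CBCT output grid
trivially the pCT grid, which downstream dose summation needs anyway.

## Registration

The clinical engine this stands in for is proprietary, so the package
implements a fully specified substitute of the same class: rigid
initialization followed by multi-resolution, compositive, demons-style
free-form registration (4 levels, 50/50/30/20 iterations).  Fields use
the pull-back convention (mm, fixed grid): `out(x) = moving(x + u(x))`.

Two similarity options handle CT↔CBCT intensity mismatch:

* **`lncc`** (default): both images are clipped to a soft-tissue window
  (−300…300 HU) and locally mean/SD-normalized (12 mm window).  The SD
  divisor is floored at 0.15× the global SD so flat, noise-dominated
  regions are damped instead of amplified to unit contrast — without
  the floor, CBCT noise drives spurious forces that visibly corrupt
  low-contrast organs.  This surrogate is exactly invariant to locally
  linear intensity maps.
* **`msq_histmatch`**: global histogram matching then mean-squares
  forces.

Update and total-field Gaussian smoothing default to 4 mm and 3 mm.
Smaller values (2 / 1.5 mm) were tried first and left noise-limited
fields on the 5×5×4 mm default grid (bladder DSC ≈ 0.85, ~0.4% of
Jacobians non-positive); the larger sigmas give bladder DSC 0.88–0.97,
landmark TRE 1.3–5.5 mm, and strictly positive Jacobians on the
default battery, so they are the shipped defaults.

When a restriction mask is supplied (e.g. the CBCT limiting contour or
FOV), fixed-image voxels *outside* the mask are replaced by the moving
image's content before the pyramid is built.  This makes the mismatch
vanish identically beyond the mask, so pyramid smoothing cannot leak
FOV-padding contrast into the interior — with identical images the
returned field is exactly zero.

Rigid registration optimizes negative normalized cross-correlation
(Powell, multi-resolution) over translations by default; the metric is
restricted to fixed-image voxels above −600 HU so FOV padding cannot
bias the optimum.  Small Euler rotations are available (`dof="rigid"`)
but the phantom's ground truth is translation-only, and the published
workflow does not state the clinical degrees of freedom.

Field algebra (`apply_dvf`, `compose`, `invert_dvf`,
`jacobian_determinant`) is tested against closed forms and against the
phantom's analytic maps.  Mask warping uses linear interpolation
thresholded at 0.5 (smoother than nearest-neighbour on curved organs).
DVF inversion is fixed-point iteration with a residual report.

## Merged CBCT

The limiting contour is the CBCT body: largest connected component
above −300 HU, morphologically closed, intersected with the valid FOV.
The pCT is deformed to the CBCT with the registration restricted to
(a dilation of) that contour; the merged volume takes CBCT voxels deep
inside the contour, warped-pCT voxels outside, and a linear alpha blend
over a 6 mm band just inside the contour (the band treatment at the
contour is not specified anywhere authoritative; the band is our
declared choice, and a per-voxel provenance label is stored).  Dose is
calculated on native CBCT HU by default — matching the workflow this
models, which did not convert CBCT HU to CT HU — while a linear HU
calibration (`fit_hu_calibration`) is available and, because the
degradation model is linear, exactly invertible in tests.

## Dose

The recalculated pathway needs a dose engine that *responds to the
anatomy of the day*; clinical algorithms are out of scope.  The engine
is a four-field box (gantry 0/90/180/270°): per beam, water-equivalent
depth is accumulated along the beam axis through the HU-derived
relative density (piecewise-linear: −1000→0.0, 0→1.0, 1000→1.6,
clamped); the depth kernel is a linear build-up ramp over 15 mm times
`exp(−0.005 mm⁻¹ · WED)`; the lateral profile is a logistic penumbra
(6 mm, 80–20) of the signed distance to the aperture (PTV projection +
7 mm margin).  The plan is normalized once, on the planning CT, so one
fraction delivers 1.8 Gy at the isocenter; that constant is frozen and
reused for every recalculation (45 Gy / 25 fractions total).  The
constants are megavoltage-like orders of magnitude and explicitly
non-clinical.

One knife-edge consequence: the in-field plateau sits at ≈100–102% of
45 Gy, and the phantom bladder only grazes the PTV, so bladder V45 can
be exactly 0 cc on the planning dose.  V45 percent differences with a
zero reference are reported as NaN rather than inventing a value.

Dose warping is trilinear pull-back resampling (out-of-bounds → 0 Gy),
without Jacobian energy weighting — conventional dose-warping practice;
the co-warping DVH test bounds the distortion (structure mean dose
invariant to 2% under the battery's fields).  Accumulation maps each
weekly dose to the week-1 reference geometry and sums with weights of
5 fractions per week (each weekly image is a surrogate for a week of
treatment; weighting is exposed because the source workflow never
states it).

## Evaluation

* **DVH metrics** use the voxel-boundary convention: voxel doses sorted
  hot-to-cold, cumulative volume through `(k·v_vox, d_(k))`, Dx/D2cc by
  linear interpolation on that axis.  A brute-force sort oracle pins
  every metric to 1e-9.
* **Bands** on |percent difference| are inclusive downward: 2.0 → "≤2",
  5.0 → "2–5"; this rule uniquely reproduces the published
  within-threshold patient counts from the bundled tables.
* **Wilcoxon signed-rank**: two-sided, zero differences dropped, ties
  midranked; exact null via a sign-flip dynamic program (doubled
  midranks stay integral) for n ≤ 25, normal approximation with tie
  correction above.
* **Gamma (3%/2 mm, 20% low-dose threshold, 90% pass level)**: global
  normalization to the reference maximum; per evaluated voxel the
  evaluated dose is minimized over a dense trilinear neighborhood
  (radius 3× the distance criterion, step ≤ criterion/10, offsets
  visited nearest-first so voxels retire once the spatial term alone
  exceeds their best gamma).  Verified against an exhaustive search and
  closed forms (uniform +3% → γ ≡ 1.0).

## Known limitations

* The phantom's deformation family is a single radial mode plus a rigid
  shift; sliding interfaces, independent rectal motion, and hysteresis
  are not modeled, so registration scores here bound only this class of
  variation.
* The dose engine has no scatter, no heterogeneity corrections beyond
  path-length scaling, and no modulation; only *relative* anatomical
  response is meaningful.
* The published patient-level dose tables cannot be recomputed from
  images (none are distributed); they are shipped as data and only
  their printed summary statistics are recomputed.
* Two published counts (rectum Dmean 11/20 within 5%, rectum D2cc 15
  within 2%) do not reproduce from the corresponding table under any
  boundary rule we tried (we obtain 13 and 14) and are excluded from
  assertions.
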