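# Methods

`archtrough` reconstructs a standard dental/mandibular arch shape and the
geometry of a panoramic focal trough from 3-D CBCT-like volumes.  This note
records the model, the estimators, the synthetic data the package is
validated against, and the numerical choices that were genuinely open.

## Anatomical frame and inputs

All geometry lives in one fixed frame: X toward the subject's left, Y
anterior, Z superior, world coordinates in mm.  Format readers (DICOM
series, NIfTI, MetaImage; via SimpleITK) normalise header orientation into
this frame.  Each subject carries ten operator landmarks: the Frankfort
orbit/meatus pair (sagittal reorientation), a coronal pair on the rami and
a sagittal pair on the occlusal plane (the two half-plane removals), the
two condyle-top points (cap removal and the binarization stop plane), and
the bilateral canine distal contact points (the superimposition anchor).

## Subject pipeline

1. **Normalization** maps intensities affinely onto [0, 1].  CBCT gray
   values are uncalibrated, so only the span matters.
2. **Frankfort reorientation** rotates the volume in the sagittal plane
   about the orbit–meatus midpoint until that line is level (trilinear
   resampling, zero fill).  The same rotation is applied to the landmarks.
3. **Confound removal.** Everything superior to the coronal line and to
   the sagittal occlusal line is zeroed (infinite-line half-plane
   semantics).  Cervical vertebrae are found on the axial MIP of the tooth
   band (occlusal plane down to one tooth length, 20 mm): after Otsu
   binarization the largest 8-connected component is taken as the arch and
   every other component with a more posterior centroid is removed,
   magnified 1.5×, through all Z.  Finally a 15 mm × 21 mm ellipse
   (anteroposterior × superoinferior) centred on each condyle point is
   zeroed through all X; the inferior edge of these ellipses defines the
   superior stop plane `stop_z` for segmentation.
4. **Cumulative binarization** thresholds axial slices from inferior to
   superior.  The first three slices use unmasked Otsu; afterwards the
   union of the previous three binary slices, magnified 1.2×, confines
   both the Otsu histogram and the admissible foreground.  Structures that
   continue smoothly up the stack are followed; structures that appear
   abruptly are suppressed.
5. **Arch image**: an axial MIP of the binary mandible over the union of
   the dental band `[occlusal − 20 mm, occlusal]` and the ramus band
   `[occlusal, stop_z]`, reduced to its largest component.  The band edges
   reuse the pipeline's own tooth-length constant and condyle stop plane.

### "Magnified to k times its original size"

Mask magnification is implemented as *equivalent-radius expansion*: the
region grows outward by `(k − 1)·sqrt(area/π)`, the distance that scales
its equivalent radius by `k`.  For a disk this is exactly similarity
scaling about the centre.  A literal similarity transform about the
region's centroid was tried first and is wrong for the mandible: scaling a
U-shaped band about its centroid displaces the limbs outward by ≈20% of
their distance to the centroid — more than the band's own half-width — so
the propagated mask stops covering the anatomy it is meant to track and
the segmentation collapses within a few slices.  Containment of the
original region is what the propagation step actually needs, and the
equivalent-radius rule provides it for arbitrary shapes while agreeing
with similarity scaling on compact ones (the vertebra footprint).

### Otsu's threshold

Implemented directly: 256 equal bins on [0, 1], every interior bin edge a
candidate split, between-class variance maximised, ties broken toward the
lower edge, foreground strictly above the threshold.  The test suite holds
it to exact agreement with an exhaustive direct-summation maximiser and
cross-checks the partition against `skimage.filters.threshold_otsu`.

## Cohort pipeline

Arches are aligned by translation only, each on the midpoint of its canine
contact points, and averaged into a per-pixel foreground-frequency map
(nearest-pixel translation keeps the masks binary; values are exact
multiples of 1/n).  The map is binarized at the grid threshold
(step 0.01) whose mask area best matches the mean individual arch area;
ties go to the candidate nearest 0.5, then lower.  With identical inputs
this reproduces each input arch exactly.

The average arch's skeleton (scikit-image, 8-connected graph via networkx)
is pruned and ordered into a single right-to-left centerline.  Three
guards deal with discrete-skeleton artifacts at blunt band ends, none of
which affect an ideal medial axis:

* spurs shorter than 5% of the skeleton length *or* 1.6× the band radius
  (distance-transform maximum) are pruned — blunt ends sprout corner
  "fishtail" branches ≈0.7 band-widths long; all short branches of an
  iteration are removed together, because removing one corner branch
  dissolves the junction and would graft its twin onto the main path;
* path ends are trimmed while the band one band-width further along is
  substantially thicker (the skeleton curling around a cap corner);
* path ends are trimmed while the local direction disagrees by more than
  ~25° with the direction one band-width inward.

The centerline is symmetrized about the vertical axis through the canine
midpoint — each point is averaged with the mirror of the point at the
complementary arc-length fraction — and each coordinate is fitted with a
cubic smoothing spline against arc length.  At every center sample the
local normal is intersected with the sub-pixel mask contour
(`skimage.measure.find_contours`); the crossing toward the arch interior
is the lingual boundary, the opposite one the buccal.  The signed offsets
are symmetrized and the boundary points spline-fitted the same way.  End
samples where the local thickness falls below 0.9× the median (plus a
1.5 mm margin) are trimmed before the final fits: where a cohort's rami
stop overlapping, the average band tapers and the skeleton chases the
ragged tip.

Smoothing uses the penalized objective `p·Σr² + (1−p)·∫f″²`
(equivalently `scipy.interpolate.make_smoothing_spline` with
`lam = (1−p)/p`; `p = 1` interpolates).  The default `p = 0.5` was chosen
on clean phantom geometry at 0.5 mm pixels: staircase skeleton noise
leaves the fitted tangent direction with ≈1° scatter at `p = 0.5` versus
≈4.5° at `p = 0.99`, while the fit still tracks the arch at the
millimetre scale.  Every fitted curve is exported as breaks plus four
cubic coefficients per piece, parameterised by arc length along the
symmetrized curve.

### Thickness profile and regional minima

Trough thickness at arc position `s` is the distance between the fitted
buccal and lingual curves at `s`; because the boundary points were
constructed along center normals, this is the normal-wise width of the
trough.  The profile runs from the anterior midline to the posterior end
of one side (the model is symmetric), with the canine arc position
splitting it into the anterior minimum (midline to canine) and posterior
minimum (canine to the posterior end).

### Arch-to-ramus transition

On each half the center is rewritten as lateral offset `x(u)` against the
posterior coordinate `u` (mm posterior to the canine).  The transition is
located at the maximum of `|d²x/du²|` — the curvature peak where the
dental arch bends outward into the ascending ramus — and its slope is
`atan(dx/du)` there, in degrees from the midsagittal axis.  Numerically:

* the curvature is read from a heavily smoothed refit (`p = 0.1`);
  second derivatives amplify pixel noise far more than the feature scale;
* the last 4 mm of the curve are excluded from the peak search and only
  interior peaks count (natural-spline end conditions and residual end
  taper make boundary second derivatives unreliable);
* the slope is the steepest lightly-smoothed tangent within 2 mm past the
  peak, clipped into a 3% band below the steepest heavily-smoothed
  tangent of the 6 mm post-transition section.  Pointwise derivatives at
  the peak itself are biased toward the arch side by smoothing; the
  section-wide estimate rides over transient overshoot of averaged
  curves; each bounds the other.

A straight center (no curvature peak above 10⁻³ mm⁻¹ anywhere posterior
to the canines) raises a no-transition error.

**What the cohort average estimates.** Binarizing the frequency map near
0.5 yields the *median* shape of the cohort, not the mean: with ten
subjects whose ramus angles spread ±2°, the median-shape transition slope
itself wobbles by up to ±2–3° around the population mean before any
estimation error.  The statistically consistent estimator of the mean
transition slope is therefore the mean of the per-subject recovered
slopes, which the recovery tests use; the cohort-average-arch slope is
reported alongside it and is checked to lie within the subjects' range.

## Synthetic phantoms

The generator renders the study conditions: a U-shaped mandibular band in
the axial plane extruded in Z (body 25 mm below the occlusal plane, rami
40 mm above), condylar knobs on the ramus tops (radius clamped to the
band half-width so their footprint stays inside the band), a soft-tissue
head ellipse, optional posterior "vertebra" cylinder and superior
"cranial" slab confounders, a smooth multiplicative low-order polynomial
bias field, and Gaussian noise.  Intensities default to bone 0.8, soft
tissue 0.12, background 0 — ordered so that slice histograms are
bone-separable, as in CT.  Defaults: parabola depth 40 mm, half-width
30 mm, ramus angle 40°, junction radius 12 mm, ramus length 20 mm, band
width 12 mm, canine 8 mm posterior of the apex, 0.5 mm isotropic voxels
on a 220×220×180 grid; noiseless and confounder-free unless asked
otherwise.  Cohorts draw each geometric parameter from a Gaussian around
the base value (fractional s.d., default 5%), redrawing invalid
geometries; each subject's noise seed is hashed from its drawn parameters
so a zero-variability cohort is bit-identical to repeated base phantoms.

The centerline has three closed-form pieces per side: a parabola
`u = a(x/b)²` whose tangent angle to the midsagittal axis falls from 90°
at the apex to `atan(b/2a)` at its end; a circular junction arc of radius
R turning the tangent outward up to the ramus angle θ (C¹ at both ends);
and a straight ramus at θ.  On the arc `|d²x/du²|` *increases* to its
maximum exactly at the arc-to-line joint, so the curvature-peak
definition of the transition has a unique analytic answer (joint location
and slope θ).  A direct tangent-continuous parabola-to-line join — the
obvious simpler choice — makes the transition ill-posed: `|x″|` then
decreases monotonically along the parabola and vanishes on the line, so
the curvature maximum sits at the anterior edge of any search window.
The junction arc also reproduces what mandibles actually show between the
molar row and the ascending ramus.

What the phantom does **not** emulate: individual teeth (the dental band
is uniform — the algorithm operates on the arch envelope), cortical/
trabecular structure, metal or scatter artifacts, head tilt (volumes are
generated Frankfort-aligned; reorientation is exercised by separate
synthetic rotations), and operator landmark error (truth landmarks are
exact; the agreement statistics exist to quantify that error on real
data).  Passing tests therefore demonstrate correct geometry recovery
under idealised segmentation conditions, not robustness to real CBCT
artifact load.

## Numerical choices and degenerate inputs

* Histogram: 256 bins on [0, 1]; Otsu ties to the lower edge; degenerate
  (single-bin) histograms raise at the API level and fall back to
  all-background inside slice iteration, with a warning.
* Connectivity: 8-connected in 2-D.
* Half-plane removal uses the infinite line; a vertical line (undefined
  superior side) is an error.  On extruded phantoms the occlusal line
  clears everything above the occlusal plane including the rami — harmless
  there because the axial footprint is carried by the sub-occlusal body,
  but stated here as a property of the literal rule.
* Symmetrization resamples to uniform arc length (odd sample count) and
  is idempotent up to piecewise-linear re-discretization (~0.01 mm).
* The area-matching threshold grid uses a 1e-9 tolerance when comparing
  frequencies (multiples of 1/n) against grid candidates.
* Pipeline determinism: every stage output is content-hashed (SHA-256)
  into the run manifest; identical inputs and configuration reproduce
  identical hashes.

## Problem sizes

Default grids (220×220×180 voxels at 0.5 mm) run one subject in ~1–2 s;
the ten-subject recovery studies used by the tests and the acceptance
script complete in well under a minute on one core.  These sizes were
chosen as the smallest grids on which voxel discretization is clearly
below all geometric tolerances (half a voxel ≪ 2 mm location tolerance).

## Known limitations

* The transition locator is tuned for a single dominant outward bend; at
  ramus angles well above 40° the longer junction arc spreads the
  curvature peak and the located point can drift ~3 mm anterior of the
  joint (slope recovery is unaffected).
* The average-arch (median-shape) transition slope inherits small-n
  sampling wobble relative to the population mean, as discussed above.
* Boundary extraction assumes each center normal crosses the mask contour
  once per side; masks with deep local concavities would need a more
  global correspondence.
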