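# Methods

`doseacc` re-implements, end to end, the analysis a dose-monitoring study
in head-and-neck radiotherapy performs: estimate, for each weekly CT of a
treatment course, the deformation back to the planning CT; pull the weekly
dose grids through those deformations onto the planning anatomy; sum them
into the cumulated dose; and score every registration method both
geometrically and dosimetrically against a reference correspondence.
This note describes the models, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Coordinate and field conventions

Volumes are regular 3-D grids with 0-based indices, axis order (x, y, z),
and world position `origin + index * spacing` (mm); no rotation matrix is
carried.  A displacement field lives on the planning grid and maps a
planning-space point `p` to the corresponding weekly-space point
`p + u(p)`.  One field per weekly CT serves both uses: pulling the weekly
dose back onto the planning anatomy (`dose'(p) = dose(p + u(p))`, trilinear,
zero-dose fill) and propagating planning landmarks into the weekly image.
Out-of-grid samples return the physical background of the unit:
−1024 HU (air), 0 Gy, 0 (label).  Label images are warped through per-code
one-hot masks thresholded at 0.5, which keeps Dice overlap stable under
sub-voxel displacements; nearest-neighbour warping was rejected because it
quantises boundary motion to whole voxels.

## The method matrix

A *method* is registration family × input preprocessing × similarity
metric.  Eleven combinations are valid: the rigid baseline
(original CTs + MSE only) and ten deformable methods — demons and
B-spline FFD, each driven by original CTs, sigmoid-filtered CTs or
delineation maps, with MSE or MI matching (MI is never paired with
delineation maps, whose integer codes are arbitrary labels).

**Sigmoid filter.** `I' = (Max−Min)·logistic((I−β)/α) + Min` with
α = 100 HU, β = 0 HU, Min = −1024 HU, Max = 2976 HU: it stretches the
soft-tissue band around 0 HU across the output window and compresses the
extreme contrast of bone and air.  The default orientation is ascending
(exponent −(I−β)/α); a config switch restores the intensity-reversing
orientation with the positive exponent, since both sign conventions
appear in the literature.

**Delineation maps.** Label images with fixed codes — skin 1, right
parotid 2, left parotid 3, brain stem 4, spinal cord 5 — registered as
intensities.  Where structures overlap the organ codes override the skin
code; among organs the higher code wins (a config-documented choice; the
organs are the registration targets).

## Rigid pre-alignment

Every weekly image is first aligned with a six-parameter transform
(translations plus intrinsic x-y-z Euler rotations about the image
centre) minimising the MSE, via fixed-step gradient descent with central
finite-difference gradients on a three-level image pyramid.  Rotations
are internally scaled by the image radius so that one parameter unit
moves a peripheral point about one millimetre; the step halves on
non-improvement and recovers by 20% per accepted step.  The rigid stage
is also evaluated as the baseline method of the matrix.

## Demons registration

Classical dense-field demons: per voxel the Thirion-normalised force

    u += (f − m) ∇f / (‖∇f‖² + (f − m)²)

(evaluated in voxel units, bounded by 0.5 voxel, additionally capped at
1.25 voxels per iteration) is added to the field, which is then smoothed
with a Gaussian of σ = 1 voxel.  Three pyramid levels; the moving image
passes through the *same* smooth-and-decimate chain as the fixed one so
that identical inputs yield identically zero forces at every level.
Two stabilisers matter on noisy data and are exposed in the config:
a σ = 1 voxel pre-smoothing of both images before force evaluation, and
a force dead-zone of 0.5% of the fixed image's robust intensity range —
without them, acquisition noise in flat soft tissue masquerades as
matching signal and the field random-walks.  Iterations default to
200/150/100 coarse-to-fine with early stopping once the MSE stops
improving by 0.01% for five iterations; the best-metric field is kept.

Delineation maps are registered at a single native-resolution level with
σ = 1.5 and 250 iterations: pyramid downsampling destroys the thin skin
shell and cord codes, and the wider regulariser suits piecewise-constant
inputs.  (The σ = 2.5 sometimes used for such inputs recovered markedly
less of the ground-truth motion on the phantom: 38% versus 51% mean
landmark-error reduction.)

## Mutual-information matching as intensity remapping

The MI-driven variants of both families are realised as histogram-based
intensity remapping followed by the MSE machinery: the moving image is
remapped through a lookup table estimated from the joint histogram of the
(lightly smoothed, σ = 0.5 voxel) fixed and moving images at the current
correspondence.  This mirrors the use of MI in this setting — the images
are the same modality, and the only systematic intensity difference is a
contrast agent present in one of them — while avoiding sampled-histogram
MI gradients, which proved numerically unstable at practical sample
counts.  The lookup is built carefully, and each ingredient earns its
place:

* **conditional median** per moving-intensity bin (384 bins), not the
  mean — a bin shared by two tissue classes keeps the majority class
  instead of averaging them into a value matching neither;
* estimated from **locally flat voxels only** (gradient below 1.2% of the
  intensity range in both images) — partial-volume voxels at strong
  interfaces sweep the entire intensity range and would otherwise flood
  the bins of genuinely low-intensity tissue such as the fat-rich
  parotid;
* **count-weighted smoothing** across bins, and empty bins fall back to
  the identity — inheriting a neighbouring tissue value would repaint
  entire boundary shells;
* an **identity gate** shrinks corrections below 1.2% of the intensity
  range — small corrections are mixed-bin bias, large ones are genuine
  systematic transforms (enhancement);
* the lookup is **refreshed at each pyramid level**, but only when the
  current field pairs the full-resolution images better (lower MSE) than
  the pairing used before — refreshing from a coarse-level field that
  pairs the images worse would bake its errors into the lookup.

## B-spline FFD registration

The deformation is a cubic tensor-product B-spline on a control-point
lattice with a one-cell margin beyond the image, refined over the grid
schedule 30 → 20 → 10 → 5 mm with a matched image pyramid
(downsampling factors 4, 2, 2, 1).  Dyadic refinements use exact
Lane-Riesenfeld subdivision (a field representable at 20 mm is
reproduced at 10 mm to machine precision); the non-dyadic 30 → 20 mm step
resamples the displacement at the new nodes and recovers coefficients
with a cubic spline prefilter.

The optimiser is a stochastic force-based scheme.  Each iteration draws
8192 random voxels, computes per-sample damped Gauss-Newton steps — the
displacement that would locally explain the residual — and scatters them
onto the lattice through the B-spline weights, normalised by the
accumulated basis mass so a control point moves by the weighted mean
force over its support.  The step size follows the adaptive gain law
`a/(t + A)^α` with a = 10⁴, A = 51, α = 0.602, where the decay time `t`
advances by a sigmoid of the correlation of successive gradients
(noise-dominated phases age the gain quickly, coherent progress keeps it
high); because the raw gain amplitude presumes a particular metric scale,
only the *shape* of the schedule is used, relative to its value at t = 0.
Updates are smoothed across the lattice (σ = 0.7 cells), capped at 2 mm
per control point per iteration, accepted only if they reduce the cost on
the same sample (rejections halve a learning-rate factor that recovers on
success), and the whole lattice is lightly smoothed every iteration
(σ = 0.4 cells) — the same force/diffusion equilibrium that regularises
demons: persistent unmatchable dents diffuse away while genuine alignment
is continually re-driven by its forces.

The force damping is deliberately metric-faithful.  The MSE variant uses
a gradient-floored step, `(f−m)∇f/(‖∇f‖² + ε²)`, which responds in full
to residuals the local gradient cannot explain — exactly as fragile to
one-sided contrast enhancement as a least-squares criterion is, and that
fragility is a finding this pipeline is built to exhibit.  The MI variant
works on remapped intensities and adds Thirion's (f−m)² damping, since
leftover unexplainable residuals (enhanced vessels) must not drag
geometry.  Several more literal optimiser designs — central finite
differences on random control-point subsets, per-control-point
Gauss-Newton with instantaneous curvature — were implemented first and
either could not move low-contrast tissue (the gradient magnitude spans
four orders of magnitude between bone edges and soft-tissue texture) or
diverged on sparsely sampled control points; the ledgered force-based
design is the package's own.

## Evaluation

*Geometric.*  Dice overlap `2|A∩B|/(|A|+|B|)` between each planning
structure and the warped weekly structure; landmark registration error as
the 3-D Euclidean distance between reference weekly positions and the
propagated planning landmarks.  *Accuracy* is the mean error over all
observations; *precision* the mean over landmarks of the per-landmark
sample standard deviation (n−1); a config option aggregates per-landmark
means first instead.

*Dosimetric.*  The reference cumulated landmark dose sums, over weeks,
the weekly dose sampled at the reference landmark positions; each
method's estimate uses its propagated positions instead, and errors are
absolute differences.  The cumulated mean parotid dose averages the
accumulated volume over the planning parotid mask.  Weekly grids carry
per-fraction dose (2 Gy scale); cumulated quantities are weighted by
`fractions / weeks` (35/6) so they live on the 70 Gy course scale, and
DVH-difference curves rescale fraction-dose axes by the fraction count.

*Method comparison.*  For every ordered method pair, an exact paired sign
test on per-(patient, week, landmark) error differences, Holm-corrected
across the family; Wilcoxon signed-rank is available.  A full
mixed-model ANOVA was deliberately not built: with a single phantom
subject the paired sign test is the assumption-light choice, and the
printed hypothesis formulations this replaces are ambiguous.

## The synthetic course

The phantom replaces an unavailable patient cohort and plays the
reference-expert role with exact ground truth.  Anatomy is analytic —
a soft-tissue ellipsoid body with vertebral column, cord, brain stem,
mandibular arch, thyroid/hyoid cartilage, sternum, carotid vessels, an
airway, and two parotid glands — rendered at 96×96×64 voxels, 2 mm
isotropic.  Soft tissue is muscle-like (≈55 HU) with an analytic random
cosine-series texture (15 HU SD, 10–40 mm wavelengths) that moves with
the anatomy, because such heterogeneity is what low-contrast registration
locks onto in real CT; the delineated organs are homogeneous (parotid
≈0 HU, fat-rich), which is both realistic and necessary for any
intensity-lookup method to tell tissues apart.  Gaussian noise (10 HU SD)
is fresh per scan.

The weekly deformation composes, with linear weekly progression to the
course totals: centripetal parotid shrinkage reaching 28.3% volume loss
(the shrink factor is calibrated numerically, by fixed-point iteration on
the Jacobian volume integral of the *composed* map, so the measured
label-map loss lands within ~1% of the target); a medial-inferior parotid
drift of (5, 0, −2) mm; lateral neck thinning of 7.9 mm total thickness;
three random smooth residual bumps (≤2 mm, σ = 25 mm, kept away from the
glands); and a per-week residual setup transform (1.5 mm / 0.5° SD) —
in-room imaging in such protocols corrects only offsets beyond a
tolerance, so mm-scale rigid offsets remain in weekly data and give the
rigid stage real work.  Composed fields are checked for invertibility
(positive Jacobian determinant; non-invertible residual draws are
rejected).  Weekly images are rendered by analytic fixed-point inversion
of the forward map, so ground-truth fields, landmark positions and label
maps are consistent by construction.

Contrast enhancement is applied to the planning image only: +100 HU in
the carotids and +75 HU in the parotids (an enhancing gland, hyperdense
relative to muscle).  The gland value is deliberately strong-but-plausible:
much below it the enhancement is invisible to MSE matching, much above it
every MSE method diverges rather than degrading the way monomodal metrics
degrade on contrast-mismatched clinical data.

Dose is analytic: a 70 Gy plateau in a spherical target abutting the left
parotid, logistic fall-off with a 5 Gy/mm maximum gradient, fixed in room
coordinates; each weekly grid carries planned/35 — the anatomy moves
through a static dose field, as delivered treatments without replanning
do.  Because the abutting gland shrinks and drifts toward the target, its
true cumulated mean dose exceeds the planned mean, the overdose mechanism
dose monitoring exists to catch.

## Validation design and problem sizes

Acceptance-style checks run the full matrix on the final week (the
largest deformation) at the package's default iteration counts, on two
controlled conditions:

* contrast off — every deformable method must halve the unregistered
  mean landmark error and beat the rigid baseline on both Dice and
  landmark error;
* contrast on — every MI variant must beat its MSE counterpart on mean
  landmark error.

The split is a factorial design, not a convenience: at this phantom's
(literature-pinned) deformation scale, a contrast mismatch strong enough
to separate the metrics also pushes MSE-on-original-CT methods below the
rigid baseline, a regime clinical cohorts with larger anatomical change
do not enter.  In-model recovery (an FFD-representable 20 mm-grid field,
≤6 mm, recovered to ≤1.5 mm RMS over the body) and self-registration
identity checks (≤0.25 voxel mean field) complete the set.

What passing these does **not** show: performance on real tissue texture,
CT artefacts, tumour regression or missing tissue (explicitly out of
scope), interobserver variability (the ground truth replaces the expert),
or dose-engine effects (weekly dose is an input contract, never computed
here).  Absolute landmark accuracies on the phantom are not comparable to
patient-cohort numbers; only the orderings and recovery fractions are
designed to transfer.

## Known limitations

* The intensity-remap realisation of MI matching is a surrogate: it
  restores a consistent intensity scale but cannot express the spatially
  varying statistical dependence a full MI metric can; small organs whose
  intensity band overlaps a dominant tissue's tail remain partially
  washed by the lookup.
* The FFD optimiser is force-based rather than a literal gradient of the
  sampled metric; its cost function is therefore implicit.
* Delineation-map registration carries no information away from the five
  coded structures; motion there is recovered only by interpolation.
* The phantom's rigid setup component and its anatomy-change magnitudes
  are fixed study conditions; conclusions are conditional on them.
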