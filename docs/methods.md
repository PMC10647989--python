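# Methods

This note records the model the package implements, the numerical choices
behind it, what the synthetic plans do and do not emulate, and the known
limitations. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dose model and coordinates

A dose distribution is a scalar field on a regular voxel grid. Internally
everything lives in metric patient coordinates (mm) with a voxel-centre
convention and axis order (x, y, z); DICOM RTDOSE frames (z, y, x) are
transposed at load, `DoseGridScaling` is applied, and only axis-aligned
orientations are accepted. Isodose levels are percent of a normalisation
dose — by default each distribution's own maximum, because the isodose set
of a plan is defined up to its D_max; normalisation to an explicit
(prescription) dose is available since verification practice varies, and
such grids may then exceed 100 %.

## Surface extraction

Isodose surfaces are extracted with marching cubes (scikit-image), i.e.
sub-voxel vertices interpolated along voxel edges. The ±1 mm tolerances at
the heart of the method demand sub-voxel geometry; voxel-membership shells
(boundary voxels of the ≥ level region) are kept as an option
(`extraction_method="voxel_shell"`) for sensitivity studies only. Surfaces
with fewer than 4 points are rejected as missing: histograms and medians
are meaningless below that size. Isodose *volumes* use plain voxel counting
of the ≥ level region — simple, conservative, and testable against analytic
spheres (the suite checks equivalent radii against closed forms to within
one voxel across levels 10–95 %).

## Histograms and their comparison

Doane's rule sets the bin count (it accounts for the skewness these
one-sided distance distributions typically have), with the adjusted
Fisher–Pearson estimator for skewness, a floor of 4 bins, and a flagged
single-bin fallback for zero-variance samples. Pairwise comparison needs
bin-wise correspondence, which leaves two free choices the method itself
does not fix:

* **Shared edges** — the bin count is anchored on the *reference* sample and
  the edge span covers the union range of both samples. Anchoring on the
  reference keeps the evaluated comparison and the tolerance limits (which
  are reference-only) on the same footing.
* **Normalisation** — counts are scaled to relative frequencies before the
  Bray–Curtis ratio (default), so the two surfaces' different vertex counts
  do not masquerade as shape difference; a raw-count mode is retained.

The hot/cold sign comes from the medians of the *raw* (unbinned) distances,
which removes binning artifacts from the sign decision; a median tie takes
the positive branch.

## Tolerance band

ISO_mr is the level whose per-percent equivalent-radius gap is closest to
the midrange (max+min)/2 of the gap curve, ties resolving to the higher
level. The radius-vs-level curve is interpolated piecewise-linearly over
integer levels and made non-increasing by isotonic clipping before use, so
voxelisation noise cannot produce negative gaps. Fractional ISO_up/ISO_low
levels are rounded to whole percent (the method operates on 1 % increments
throughout); levels whose rounded tolerance partners coincide with the
level itself, fall outside the grid, or yield a zero limit are dropped from
the chart with a warning — a fabricated default limit would mask errors.
On multi-target plans whose gap curve crosses the midrange repeatedly, the
automatic choice returns the single closest level; `iso_mr_override` and a
`level_range` argument support a user-designated ISO_mr per target.

One asymmetry in the normalisation is implemented exactly as defined even
though it is geometrically debatable: hot deviations (evaluated surface
farther out, resembling the ISO_low side) are normalised by BC_ISOup. On
near-symmetric gradients the two limits differ little; a
`swap_limit_pairing` switch implements the alternative pairing for
sensitivity analysis.

## Synthetic plans

The generator stands in for phantom verification plans: radially structured
fields on a default 1×1×1 mm grid with closed-form isodose radii — spheres
and ellipsoids with linear, quadratic or sigmoid falloff, a two-lobe
dual-target analogue, optional analytic rotation about the isocenter
(applied while sampling, so rotated plans carry no resampling error), and
optional Gaussian dose noise (off by default; planned dose is smooth).
Rigid shifts follow the error-induction protocol: the field is translated
with tricubic resampling in 1 mm steps along the lateral/vertical/
longitudinal axes or composites, while the isocenter metadata stays fixed —
the error is in the delivered dose, not in the registration.

What these plans do *not* emulate: beam-model texture, heterogeneity,
noise-like TPS artefacts, and above all the broad, irregular isodoses of
clinical plans. That last gap matters for interpretation:

* A *perfect sphere's* isocentric distance histograms are delta-like
  (width ~0.1–0.2 mm). Its ±1 mm tolerance shells are then already
  disjoint (BC limits ≈ 1), and the Bray–Curtis value against any shifted
  copy is essentially shift-independent (the shared-bin width grows with
  the shift while the shifted distribution's density falls inversely, and
  the two effects cancel), so mean |ISD| sits on a ≈ 93 % plateau for
  shifts ≥ 1 mm with sub-percent bin-phase wiggles. Passing or failing a
  monotone-growth check on a perfect sphere therefore says nothing about
  real plans.
* The *anisotropic ellipsoid* has broad histograms (tens of mm) and is the
  right object for sensitivity properties: mean |ISD| grows monotonically
  with shift magnitude over 1–5 mm on every axis, and the fitted slope of
  the long (shallow-gradient) axis is clearly smaller than the steep axes',
  so the error direction is distinguishable. Both are asserted in the
  engine tests.

## Rotation pre-flight check

Isocentric distances are invariant under any rotation about the isocenter —
the parametrization's one blind spot. The check compares reference and
evaluated histograms at the 50/75/80/90 % isodoses from the isocenter and
from three seeded random non-coplanar probe points (drawn uniformly in the
50 % isodose bounding box; non-coplanarity enforced by a minimum
tetrahedron volume of 1 mm³ with bounded retries).

Two numerical facts shape the decision rule. First, "identical up to
discretisation" is not BC = 0: binning a surface extracted from a voxel
grid carries a quadrature floor of roughly k·δ/range (k bins, δ the
sub-voxel vertex position error), ~1–2 % at 1 mm voxels — measured at
0.010–0.023 for analytically rotated plans, and insensitive to area
weighting or spline refinement of the vertices, since it scales with voxel
size. Second, a rotation is the one error that leaves the isocentric value
*at* that floor while the probes disagree with it several-fold (measured
5–9× for a 15° rotation), whereas translations and genuine shape errors
move all four parametrization points together (probe/iso ratios ≈ 1.2–1.7
for 1–2 mm shifts). The rule is therefore: a level is suspicious when the
isocentric BC is below ε = 0.03 *and* the best probe exceeds
max(ε, 2 × iso BC); any suspicious level flags the comparison. Both
constants are parameters; ε sits between the observed floor and the
smallest observed rotation signals. Rotations too small to lift a probe
above ε (~a few degrees on typical geometry) are below this check's
resolution; estimating the rotation angle or axis is out of scope.

## Gamma baseline

The global-normalisation gamma index (default 3 % of the reference maximum,
2 mm DTA, 10 % low-dose cutoff, 95 % acceptance) is computed by embedding
the evaluated field, resampled to steps of DTA/3 per axis by default
(linear interpolation), into the scaled 4D space (x/dta, y/dta, z/dta,
D/ΔD) and taking each reference voxel's nearest-neighbour distance with a
KD-tree capped at γ = 2. Discrete sampling makes this a slight upper bound
on the continuum gamma; at DTA/10 sampling it agrees with a brute-force
dense-search evaluation of the definition to within 0.5 percentage points
on the suite's synthetic cases. The pipeline reports gamma but does not
gate the verdict on it — ISD stands alone or as an auxiliary check.

## Problem sizes and determinism

The test suite and the acceptance script use grids between 25³ and 201³ at
1 mm spacing: 64³ for identity checks, 101³ (linear falloff over 50 mm,
whose r(x) = 50 − x/2 makes the ±1 mm interval exactly 2 percentage
points) for tolerance and saturation checks, 201³ (r(x) = 100 − x, interval
exactly 1 point) for the tolerance-geometry check, and ~121×111×101 for
rotation checks. On a linear radial plan every level has the same gradient,
so the automatic midrange selection of ISO_mr rides on voxel noise; those
checks pass `iso_mr_override=50` — a documented configuration choice, not a
calibration. All randomness (probe draws, optional noise) flows through
explicit seeds; marching cubes, binning and Bray–Curtis are deterministic,
so self-comparisons yield exactly zero.

## Known limitations

* ISD reports *that* and *how much* an isodose's shape deviates, not
  *where* on the surface — localisation needs second-level processing.
* The isocenter must sit reasonably centrally; for off-centre or multiple
  isocenters a central reference point should be supplied instead (the
  parametrization point is an argument throughout).
* Mirror-image distributions share isocentric histograms (same blind-spot
  family as rotations); the probe check covers rotations only.
* Tolerance limits depend on vertex counts and voxel size through the
  histograms; comparing plans computed on very different grids is not
  supported.
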