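# Methods

This note documents the measurement models implemented in `atriometry`,
the conventions chosen where several readings were possible, what the
synthetic phantoms do and do not emulate, and the numerical choices that
affect results.

## Chamber representation and units

A chamber surface is a watertight triangle mesh (`TriMesh`): vertices in
mm, faces as counter-clockwise index triples viewed from outside.
Watertightness is checked combinatorially — every directed edge must be
matched by its reverse exactly once — so inconsistently wound or doubled
faces fail the same check as open boundaries. Clinical LA segmentations
have mitral, pulmonary-vein, and appendage openings; those surfaces must
be capped upstream before volume or sphericity computation, and the
error message says how many edges are open. Faces with relative area
below 10⁻¹² of the mean face area are rejected as degenerate at
construction. Coordinates are mm, areas mm², volumes mL (mm³/1000)
throughout.

Volume is the absolute value of the divergence-theorem sum
`Σ v₀·(v₁×v₂)/6` over faces, so either consistent global orientation is
accepted. Surface area is the plain sum of triangle areas and does not
require watertightness.

## Sphericity indices

**3DS** compares the chamber's surface area with that of the equal-volume
sphere: `3DS = 100·π^(1/3)(6V)^(2/3)/A`. It is scale-invariant and, by
the isoperimetric inequality (which holds for polyhedra as well as smooth
surfaces), never exceeds 100 %.

**LASP** measures scatter of the surface about a best-fit sphere. Two
details are under-determined in the literature and are fixed here as
constants of the method:

- the *center of mass* is the area-weighted mean of triangle centroids
  (a surface centroid, not a volumetric one) — the algorithm is phrased
  entirely in terms of triangles and their areas, and the surface
  centroid keeps the whole computation consistent under one weighting;
- the *radius of a triangle* is the distance from that center of mass to
  the triangle centroid (not to its vertices), matching the
  area-weighting naturally.

Then `AR` is the area-weighted mean radius, `CVS` the area-weighted SD of
radii divided by `AR`, and `LASP = (1 − CVS)·100`. Because the root of
summed squared deviations penalizes anisotropy more strongly than the
area ratio does, LASP sits below 3DS on every elongated phantom (verified
for aspect ratios ≥ 1.2); the package asserts no ordering in general.
Both indices are scale- and rigid-motion-invariant to better than 10⁻⁹
relative.

## Volumetry

Slice summation treats each contour as a slab: `V = Σ Aᵢ(tᵢ+gᵢ)`. The
inter-slice gap defaults to 0 (a convention — contiguous slabs — not a
claim about any particular acquisition protocol). Sampled midpoint-rule
stacks converge to the mesh volume first-order in thickness.

The biplane area-length estimate `8/(3π)·A₁A₂/L` takes `L` as the
shorter of the two measured lengths, exactly as the formula is
conventionally written. The formula is exact for ellipsoids sectioned
through principal long-axis planes, which the test suite exploits.

Cycle extremes: the maximum-volume frame is the arithmetic argmax over
the series — an automated stand-in for the visual frame selection a
human reader performs; the minimum is the first frame of the cycle by
default (`first-frame` rule), with a `global` rule selectable. Cyclic
change is max − min and the expansion index is change/min.

Body surface area uses Mosteller √(kg·cm/3600) by default (Du Bois
selectable); no particular formula is canonical for CMR indexing, and the
choice only affects enlargement classification, whose thresholds are
inclusive (≥): 54 mL/m² (women) and 53 mL/m² (men) for slice-summation
volumes, 55 mL/m² for ventricle-oriented biplane volumes for both sexes,
and no classification for atrium-oriented biplane volumes, for which no
published upper normal limit exists.

## Axis angles

The LA axis runs mitral-ring center → dorsal LA; the LV axis runs
mitral-ring center → LV apex, both anchored at the mitral center of the
phase being measured. Anatomically the two chambers lie on opposite
sides of the mitral ring, so parallel long axes mean *anti-parallel*
direction vectors; the deviation angle is therefore reported as 180°
minus the raw vector angle, making 0° = parallel anatomy. Cyclic angle
change is signed ED − ES (positive when the axes are more aligned at
end-systole).

The rotation angle is the dihedral between the 4-chamber plane (apex, ED
mitral center, lateral RV wall) and the plane containing both long axes
(apex, ED mitral center, dorsal LA), folded to [0, 90]° by default since
no sign convention is established; a signed variant (sign = side of the
4CH plane on which the dorsal LA lies, positive along the normal of the
ordered triple apex–mitral–RV) is opt-in. The rotation angle is defined
at end-diastole only. Collinear defining triples raise an error naming
the degenerate plane; in particular, anatomy with deviation angle 0 puts
the dorsal LA on the LV axis and leaves the rotation angle undefined.

Both angles are invariant under rigid motion and uniform scaling of all
landmarks (tolerance 10⁻⁹ degree).

## Agreement statistics

Bland–Altman differences are oriented calculated − reference, matching
the signed volume-error convention. Limits of agreement use a multiplier
of 2 (not 1.96), configurable. The bias CI uses the t distribution with
n−1 df — standard practice at the n = 20–60 sizes these comparisons run
at; no closed form is canonical for the printed CIs this mirrors, and the
t choice is documented rather than asserted. ICC(3,1) is computed from
the two-way ANOVA decomposition,
`ICC = (MS_B − MS_E)/(MS_B + (k−1)·MS_E)`, with the Shrout–Fleiss
F-bound 95 % CI; it is a consistency coefficient, invariant to adding a
constant to one rater's column. Shapiro–Wilk normality testing is
delegated to scipy; the normality gate (α = 0.05) selects mean ± SD
versus median with Tukey-hinge IQR in summaries.

## Synthetic phantoms: what they emulate, and what they do not

`make_phantom` maps a subdivided icosphere onto an ellipsoid and adds
seeded smooth radial bumps (a sum of von-Mises–Fisher-shaped lobes,
normalized to the requested amplitude, capped at 0.3 of local radius so
the surface stays star-shaped and watertight). With no bumps and ≥ 4
subdivisions the mesh volume is within 0.5 % of 4πabc/3. These phantoms
have analytically known geometry, which is what makes the validation
chain closed — but they are smooth, star-shaped, and hole-free, unlike
real atria with appendage lobes, vein ostia, and regional wall
deformity. Passing tests therefore demonstrate correctness of the
*measurement operators*, not robustness to real anatomical complexity.

`make_landmarks` constructs anatomy with exactly prescribed angles (the
inverse of the angle measurements): ED mitral center at the origin, LV
axis along +z, 4CH plane = x–z plane, dorsal LA at spherical angles
(θ, φ). The ES mitral center moves apically by 15 % of the LV length by
default; when a target ES angle is prescribed, an additional lateral
in-plane displacement is solved by bisection (pure axial displacement
cannot reach arbitrarily small ES angles, so the solver keeps the axial
shortening and adjusts laterally — exact to the solver tolerance
10⁻¹³).

**Biplane sampling and foreshortening.** `sample_biplane` cuts two
planes containing a given axis (default separation 60°, the nominal
2CH/4CH configuration, configurable) through a neutral anchor at the
surface center of mass; for a spheroid sampled along its true long axis
this reproduces the analytic volume to mesh tolerance. The clinically
relevant misalignment case is different: ventricle-oriented planes pivot
at the *mitral ring*, i.e. at the chamber's end, not its center.
`lv_oriented_biplane` therefore anchors the tilted axis at the
ventricular end of the chamber (`mitral_anchor`, 5 % inset). Off-center
oblique sections are strictly smaller, and the resulting biplane volume
underestimates the true volume in every tested configuration (tilts
10–30°, arbitrary azimuths and plane offsets) — the mechanism behind the
negative bias of ventricle-oriented biplane volumetry. Center-anchored
tilted sections do *not* reliably underestimate (the chord in the
denominator can shrink faster than the areas), which is why the pivot
location is part of the model and documented here.

`make_cohort` draws per-subject targets from the distributions typical
of a 60-subject adult population without structural heart disease
(maximum LA volume 88.4 ± 18.0 mL, ED deviation angle 28.3 ± 6.2°,
rotation 20.5 ± 18.0° folded to ≥ 0, end-systolic 3DS 85.6 ± 3.2 %,
weight 82.8 ± 17.7 kg, height 173 ± 9 cm), builds a prolate-spheroid
phantom per subject (aspect ratio inverted numerically from the drawn
3DS target; size rescaled so the *measured* mesh volume equals the drawn
volume) and a landmark set with the drawn angles, then re-derives every
reported measurement by running the pipeline on those artifacts. A
single shared latent factor induces the small negative correlation
(r ≈ −0.35) between ED angle and indexed maximum volume; no fuller
covariance model is attempted. The ventricle-oriented biplane volume per
subject uses the subject's own ED angle as tilt; with strongly prolate
phantoms this foreshortening bias is larger in magnitude than in real
atria — the cohort demonstrates the direction and mechanism of the
bias, not its clinical magnitude. LASP of a prolate spheroid at 3DS ≈
86 % is ≈ 67 %, lower than real atria score, because real chambers are
compact-irregular rather than elongated; the cohort controls 3DS, and
LASP follows the shape family.

Default problem sizes (icosphere subdivision 4 ≈ 5 120 faces, 100
phantoms for the isoperimetric sweep, 20 for the foreshortening suite,
n = 10 000 for Monte-Carlo statistic recovery, 60-subject cohort) keep
the complete validation run in well under a minute while leaving
Monte-Carlo standard errors far smaller than the tolerances being
checked.

## Known limitations

- No image segmentation: meshes, contours, and landmarks arrive
  pre-delineated.
- Open clinical meshes must be capped before volumetry/sphericity; the
  package validates but does not repair.
- No regional wall-deformity or asymmetry mapping; sphericity indices
  summarize departure from a sphere without localizing it.
- No three-plane (2CH/3CH/4CH) area-length variant.
- The cohort generator's correlation structure is a single-factor
  construction; only the sign/magnitude of a few associations is
  emulated.
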