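# atriometry

Left atrial (LA) volumetry and shape analysis for cardiac-MRI-derived
geometry: 3D slice-summation and biplane area-length volume determination,
two triangle-mesh sphericity indices, 3D LA–LV axis angles from anatomical
landmarks, and the agreement statistics (Bland–Altman, intraclass
correlation) used to compare measurement methods. Because accurate LA
volume matters clinically but 2D calculation methods rest on geometric
assumptions, the package also ships seeded synthetic phantoms with
analytically known volume and shape, so every stage of the pipeline can be
validated end to end without any imaging data.

Intended for researchers in cardiac imaging methodology who work with
segmented chamber surfaces (PLY/STL/OFF meshes), per-slice contour areas,
and 3D landmark coordinates.

## Methods at a glance

**Volumes.** The reference volume is slice summation over a short-axis
contour stack, `V = Σᵢ Aᵢ·(tᵢ + gᵢ)` (area × slab height, mm³ → mL). The
biplane area-length estimate from two long-axis views is

```
V = 8/(3π) · A₁·A₂ / L,     L = min(L₁, L₂),
```

with `A₁, A₂` the planimetry areas and `L` the shorter of the two measured
long-axis lengths. The signed calculated-volume error is calculated minus
reference. Volumes are indexed to body surface area (Mosteller by default)
and classified against published enlargement cut-offs (≥ 54/53 mL/m² for
women/men by slice summation, ≥ 55 mL/m² for ventricle-oriented biplane
volumes; no threshold exists for atrium-oriented biplane volumes).

**Sphericity.** For a watertight chamber mesh with volume `V` and surface
area `A`:

- 3D sphericity `3DS = 100·π^(1/3)·(6V)^(2/3)/A` — the surface area of the
  equal-volume sphere over the actual surface area; ≤ 100 % by the
  isoperimetric inequality;
- LA sphericity `LASP = (1 − CVS)·100`, where `CVS` is the area-weighted
  coefficient of variation of the distances from the surface center of
  mass to the triangle centroids (the best-fit sphere has its center at
  the center of mass and radius `AR`, the area-weighted mean distance).

**Axis angles.** From five landmarks (dorsal LA, mitral-ring center at
ED/ES, LV apex, lateral RV wall): the LA–LV deviation angle between the
mitral→dorsal-LA and mitral→apex lines (0° = anatomically parallel axes),
its ED−ES cyclic change, and the LA rotation angle — the dihedral angle
between the 4-chamber plane and the plane containing both long axes.

**Agreement.** Bland–Altman bias with t-based 95 % CI and limits of
agreement at bias ± 2·SD, and ICC(3,1) (two-way mixed, consistency,
single measures) with Shrout–Fleiss F-bound CIs.

## Worked example

Generate a bumpy ellipsoidal LA phantom (semiaxes 24 × 14 × 12 mm), measure
its shape, slice it short-axis style, and recover its volume:

```
$ atriometry simulate phantom --a 24 --b 14 --c 12 --bump-amplitude 0.12 \
      --seed 7 --out la.ply
wrote la.ply (volume 17.0 mL, seed 7)

$ atriometry sphericity --mesh la.ply
volume_mL: 17.0
surface_area_mm2: 3419.1
three_ds_pct: 93.5
lasp_pct: 79.8
ar_mm: 16.70
cvs: 0.2020

$ atriometry simulate contours --mesh la.ply --thickness 1 --axis 1 0 0 \
      --out stack.csv
wrote stack.csv (49 slices, 17.0 mL)
```

The phantom's 3DS of 93.5 % says its surface area is ~7 % larger than the
equal-volume sphere's; the stricter best-fit-sphere index LASP (79.8 %)
penalizes the same radial irregularity more heavily. The 1 mm contour
stack recovers the mesh volume to within rounding.

Landmarks constructed with a prescribed geometry are inverted exactly by
the angle measurements:

```
$ atriometry simulate landmarks --theta 28.3 --phi 20.5 --theta-es 21.1 \
      --out lm.csv
$ atriometry angles --landmarks lm.csv
la_lv_angle_ed_deg: 28.3
la_lv_angle_es_deg: 21.1
cyclic_angle_change_deg: 7.2
la_rotation_angle_deg: 20.5
```

And a simulated repeatability experiment (20 subjects, injected bias
−0.9 mL, error SD 3 mL) analyzed with Bland–Altman and ICC:

```
$ atriometry simulate raters --n 20 --bias -0.9 --sd 3.0 --seed 5 \
      --out raters.csv
$ atriometry agree --table raters.csv
comparison: test - reference (n=20)
bias: -2.3 (-3.2 to -1.3)
limits_of_agreement: (-6.4 to 1.9)
icc31: 0.99 (0.98-1.00) *
```

With n = 20 and SD 3 mL the recovered bias scatters around the injected
−0.9 mL with a standard error of 0.67 mL, as here.

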