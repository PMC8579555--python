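"""Seeded synthetic-data generators for every pipeline input.

No deposited imaging dataset accompanies this package, so each analysis
stage is exercised on phantoms with analytically known geometry:

* near-ellipsoidal watertight chamber surfaces with controllable volume,
  aspect ratio, and smooth radial surface bumps;
* short-axis contour stacks sampled from those surfaces;
* biplane long-axis sections (areas and axis lengths) including
  deliberately tilted sampling axes that reproduce foreshortening;
* landmark sets constructed to yield prescribed LA–LV deviation and
  rotation angles exactly (the inverse of the angle measurements);
* paired-rater tables with prescribed bias and error SD;
* a demo cohort whose per-variable distributions mirror a typical
  adult study population (n = 60 by default).

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .axes import LandmarkSet, analyze_landmarks
from .mesh import TriMesh, center_of_mass, lasp, mesh_volume, plane_section
from .stats import PairedMeasurements
from .volumetry import (
    BiplaneMeasurement,
    ContourStack,
    Slice,
    VolumeMethod,
    biplane_volume,
    body_surface_area,
    index_volume,
)

import trimesh as _trimesh

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "make_landmarks",
    "sample_contours",
    "sample_biplane",
    "mitral_anchor",
    "lv_oriented_biplane",
    "make_paired_raters",
    "make_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one near-ellipsoidal chamber phantom.

    semiaxes in mm; ``bump_amplitude`` is the maximum radial perturbation
    as a fraction of the local radius (capped at 0.3 so the surface stays
    star-shaped and watertight); ``rotation`` is an optional 3x3 matrix
    and ``translation`` an optional offset applied after shaping.
    """

    semiaxes: tuple = (20.0, 15.0, 10.0)
    bump_amplitude: float = 0.0
    bump_count: int = 6
    subdivisions: int = 4
    rotation: tuple | None = None
    translation: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        ax = tuple(float(a) for a in self.semiaxes)
        if len(ax) != 3 or any(a <= 0 for a in ax):
            raise ValueError(f"semiaxes must be three positive lengths, got {ax}")
        if not 0.0 <= self.bump_amplitude <= 0.3:
            raise ValueError(
                f"bump_amplitude must lie in [0, 0.3], got {self.bump_amplitude}"
            )
        if self.subdivisions < 1:
            raise ValueError("subdivisions must be >= 1")
        if self.bump_count < 0:
            raise ValueError("bump_count must be >= 0")
        object.__setattr__(self, "semiaxes", ax)

    @property
    def analytic_volume_ml(self) -> float:
        """4/3 pi a b c in mL; exact only when bump_amplitude = 0."""
        a, b, c = self.semiaxes
        return 4.0 * np.pi * a * b * c / 3.0 / 1000.0


def make_phantom(spec: PhantomSpec) -> TriMesh:
    """Watertight near-ellipsoidal phantom mesh.

    A subdivided icosphere is mapped to the ellipsoid with the requested
    semiaxes; seeded smooth radial bumps (a sum of von-Mises–Fisher-shaped
    lobes on the sphere, normalized to the requested amplitude) emulate
    anatomical departures from the ideal shape.  Fixed seed gives
    bit-identical vertices.
    """
    ico = _trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    dirs = np.asarray(ico.vertices, float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    radial = np.ones(len(dirs))
    if spec.bump_amplitude > 0 and spec.bump_count > 0:
        rng = np.random.default_rng(spec.seed)
        centers = rng.normal(size=(spec.bump_count, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        signs = rng.choice([-1.0, 1.0], size=spec.bump_count)
        kappa = rng.uniform(4.0, 12.0, size=spec.bump_count)  # lobe sharpness
        f = np.zeros(len(dirs))
        for c, s, k in zip(centers, signs, kappa):
            f += s * np.exp(k * (dirs @ c - 1.0))
        peak = np.abs(f).max()
        if peak > 0:
            radial += spec.bump_amplitude * f / peak

    verts = radial[:, None] * dirs * np.asarray(spec.semiaxes)
    mesh = TriMesh(verts, np.asarray(ico.faces, np.int64))
    rot = np.asarray(spec.rotation, float) if spec.rotation is not None else None
    tra = np.asarray(spec.translation, float) if spec.translation is not None else None
    if rot is not None or tra is not None:
        mesh = mesh.transformed(rotation=rot, translation=tra)
    return mesh


def make_landmarks(
    theta: float,
    phi: float,
    lv_length: float = 80.0,
    la_length: float = 50.0,
    es_shortening: float = 0.15,
    theta_es: float | None = None,
    rv_offset: float = 40.0,
) -> LandmarkSet:
    """Landmark set with prescribed deviation and rotation angles.

    The ED mitral center sits at the origin with the LV apex at
    ``lv_length`` along +z, so the LV long axis is the z axis; the lateral
    RV point lies in the x–z plane, making that plane the 4-chamber plane.
    The dorsal LA point is placed at ``la_length`` from the mitral center
    so that the ED LA–LV deviation angle equals ``theta`` and the rotation
    angle to the 4CH plane equals ``phi`` exactly.

    The ES mitral center is displaced toward the apex along the LV axis by
    ``es_shortening * lv_length`` (the mitral annulus moves apically in
    systole, which aligns the axes).  When ``theta_es`` is given, an
    additional lateral displacement within the axes plane is solved for so
    that the ES deviation angle equals ``theta_es`` exactly.

    ``theta = 0`` yields collinear anatomy: the deviation angle is 0 but
    the rotation angle is then geometrically undefined.
    """
    if not 0.0 <= theta < 90.0:
        raise ValueError(f"theta must lie in [0, 90), got {theta}")
    if not 0.0 <= phi <= 90.0:
        raise ValueError(f"phi must lie in [0, 90], got {phi}")
    if lv_length <= 0 or la_length <= 0:
        raise ValueError("axis lengths must be positive")

    th = np.radians(theta)
    ph = np.radians(phi)
    mitral_ed = np.zeros(3)
    apex = np.array([0.0, 0.0, lv_length])
    rv = np.array([rv_offset, 0.0, 0.5 * lv_length])
    dorsal = la_length * np.array(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), -np.cos(th)]
    )

    s = es_shortening * lv_length
    if theta_es is None:
        mitral_es = np.array([0.0, 0.0, s])
    else:
        if not 0.0 < theta_es < 90.0:
            raise ValueError(f"theta_es must lie in (0, 90), got {theta_es}")
        lateral = np.array([np.cos(ph), np.sin(ph), 0.0])  # within the axes plane

        def _es_angle(x: float) -> float:
            mc = x * lateral + np.array([0.0, 0.0, s])
            u = dorsal - mc
            v = apex - mc
            cosang = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
            return 180.0 - np.degrees(np.arccos(cosang))

        # x0 puts the ES mitral center on the apex–dorsal line (angle 0);
        # the angle grows monotonically as x decreases from x0
        x0 = (lv_length - s) * la_length * np.sin(th) / (
            (lv_length - s) + la_length * np.cos(th) + s
        )
        lo = 0.0
        target = float(theta_es)
        for _ in range(60):
            if _es_angle(lo) >= target:
                break
            lo -= 0.2 * lv_length
        else:
            raise ValueError(
                f"theta_es={theta_es} not reachable by mitral displacement"
            )
        x = brentq(lambda t: _es_angle(t) - target, lo, x0, xtol=1e-13)
        mitral_es = x * lateral + np.array([0.0, 0.0, s])
    return LandmarkSet(
        dorsal_la=dorsal,
        mitral_center_ed=mitral_ed,
        mitral_center_es=mitral_es,
        lv_apex=apex,
        rv_lateral=rv,
    )


def _perpendicular_basis(axis: np.ndarray) -> tuple:
    """Deterministic orthonormal pair spanning the plane normal to ``axis``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def sample_contours(mesh: TriMesh, slice_thickness: float, axis) -> ContourStack:
    """Short-axis contour stack sampled from a phantom.

    Parallel planes perpendicular to ``axis`` at slab centers spanning the
    mesh extent; per-slice areas come from exact mesh cross-sections, so
    the summed stack volume converges to the mesh volume as the thickness
    shrinks (midpoint rule, first order in thickness).
    """
    if slice_thickness <= 0:
        raise ValueError(f"slice thickness must be positive, got {slice_thickness}")
    ax = np.asarray(axis, float)
    ax = ax / np.linalg.norm(ax)
    e1, _ = _perpendicular_basis(ax)
    proj = mesh.vertices @ ax
    zmin, zmax = float(proj.min()), float(proj.max())
    n_slices = max(1, int(np.ceil((zmax - zmin) / slice_thickness)))
    slices = []
    for i in range(n_slices):
        z = zmin + slice_thickness * (i + 0.5)
        sec = plane_section(mesh, z * ax, ax, e1)
        slices.append(Slice(area=sec.area, thickness=slice_thickness))
    return ContourStack(slices=tuple(slices), phase_label="phantom")


def sample_biplane(
    mesh: TriMesh,
    axis,
    rotation_offset: float = 0.0,
    inter_plane_angle: float = 60.0,
    anchor=None,
) -> BiplaneMeasurement:
    """Biplane planimetry of a phantom along a chosen long axis.

    Two planes containing the axis line through ``anchor`` (default: the
    surface center of mass), separated by ``inter_plane_angle`` degrees
    about it — the nominal 2CH/4CH configuration is 60 degrees.  Areas
    come from the plane sections and lengths from the section extent along
    the axis.  Sampling along an axis tilted off the chamber's true long
    axis foreshortens both, which is the mechanism behind the negative
    bias of ventricle-oriented biplane volumes.
    """
    ax = np.asarray(axis, float)
    ax = ax / np.linalg.norm(ax)
    if anchor is None:
        anchor = center_of_mass(mesh)
    anchor = np.asarray(anchor, float)
    e1, e2 = _perpendicular_basis(ax)

    def _cut(angle_deg: float):
        a = np.radians(angle_deg)
        in_plane = np.cos(a) * e1 + np.sin(a) * e2
        normal = np.cross(ax, in_plane)
        sec = plane_section(mesh, anchor, normal, ax)
        if sec.is_empty:
            raise ValueError("sampling axis misses the mesh: empty section")
        return sec.area, sec.max_chord

    a1, l1 = _cut(rotation_offset)
    a2, l2 = _cut(rotation_offset + inter_plane_angle)
    return BiplaneMeasurement(a1=a1, a2=a2, l1=l1, l2=l2,
                              orientation=VolumeMethod.AL_LV)


def mitral_anchor(mesh: TriMesh, long_axis, inset: float = 0.05) -> np.ndarray:
    """Pivot point for ventricle-oriented sampling of a phantom.

    The mitral ring sits at the chamber's ventricular end, so misaligned
    long-axis planes pivot there rather than at the chamber center.  The
    anchor is the point on the chamber's long axis at the ventricular
    (negative-axis) end of the mesh extent, pulled inward by ``inset`` of
    the half-extent so the sampling planes still intersect the surface.
    """
    ax = np.asarray(long_axis, float)
    ax = ax / np.linalg.norm(ax)
    com = center_of_mass(mesh)
    proj = (mesh.vertices - com) @ ax
    return com + (1.0 - inset) * float(proj.min()) * ax


def lv_oriented_biplane(
    mesh: TriMesh,
    long_axis,
    tilt_deg: float,
    azimuth_deg: float = 0.0,
    rotation_offset: float = 0.0,
    inter_plane_angle: float = 60.0,
) -> BiplaneMeasurement:
    """Biplane sampling along a ventricle-oriented (misaligned) axis.

    The sampling axis is the chamber's true long axis tilted by
    ``tilt_deg`` (about a direction set by ``azimuth_deg``), pivoting at
    the mitral end of the chamber.  Off-center, obliquely cut sections
    have smaller areas and shorter axis chords — the foreshortening that
    biases ventricle-oriented biplane volumes negative.
    """
    ax = np.asarray(long_axis, float)
    ax = ax / np.linalg.norm(ax)
    e1, e2 = _perpendicular_basis(ax)
    t = np.radians(tilt_deg)
    a = np.radians(azimuth_deg)
    tilted = np.cos(t) * ax + np.sin(t) * (np.cos(a) * e1 + np.sin(a) * e2)
    return sample_biplane(
        mesh,
        tilted,
        rotation_offset=rotation_offset,
        inter_plane_angle=inter_plane_angle,
        anchor=mitral_anchor(mesh, ax),
    )


def make_paired_raters(
    n: int,
    bias: float,
    sd: float,
    base_mean: float = 88.4,
    base_sd: float = 18.0,
    seed: int = 0,
    label_x: str = "test",
    label_y: str = "reference",
) -> PairedMeasurements:
    """Paired measurements with prescribed bias and error SD.

    The reference rater draws y_i ~ Normal(base_mean, base_sd^2); the test
    rater re-measures with x_i = y_i + bias + eps_i, eps ~ Normal(0, sd^2),
    so Bland–Altman on (x, y) recovers the injected bias and SD.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 pairs, got {n}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    rng = np.random.default_rng(seed)
    y = rng.normal(base_mean, base_sd, size=n)
    x = y + bias + rng.normal(0.0, sd, size=n)
    return PairedMeasurements(x=x, y=y, label_x=label_x, label_y=label_y)


# ---------------------------------------------------------------------------
# demo cohort


@dataclass(frozen=True)
class CohortSpec:
    """Distributional targets for a demo study cohort.

    Defaults mirror a 60-subject adult population free of structural heart
    disease: mean maximum atrial volume 88.4 ± 18.0 mL, minimum
    38.6 ± 10.7 mL, ED deviation angle 28.3 ± 6.2 deg with a cyclic change
    of 7.3 ± 4.7 deg, rotation angle 20.5 ± 18.0 deg (folded to >= 0), and
    an end-systolic 3D sphericity of 85.6 ± 3.2 %.  ``angle_volume_r``
    induces the small negative correlation between the ED deviation angle
    and the indexed maximum volume via a shared latent factor.
    """

    n: int = 60
    max_lav_ml: tuple = (88.4, 18.0)
    min_lav_ml: tuple = (38.6, 10.7)
    minmax_corr: float = 0.7
    ed_angle_deg: tuple = (28.3, 6.2)
    cyclic_angle_deg: tuple = (7.3, 4.7)
    rotation_deg: tuple = (20.5, 18.0)
    three_ds_pct: tuple = (85.6, 3.2)
    weight_kg: tuple = (82.8, 17.7)
    height_cm: tuple = (173.0, 9.0)
    angle_volume_r: float = -0.353
    subdivisions: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"cohort needs n >= 2, got {self.n}")
        for name in ("max_lav_ml", "min_lav_ml", "ed_angle_deg",
                     "cyclic_angle_deg", "rotation_deg", "three_ds_pct",
                     "weight_kg", "height_cm"):
            mean, sd = getattr(self, name)
            if sd <= 0:
                raise ValueError(f"{name} SD must be positive")
        if self.three_ds_pct[0] >= 100.0:
            raise ValueError("target 3D sphericity must be < 100%")
        if not -1.0 < self.angle_volume_r < 1.0:
            raise ValueError("angle_volume_r must lie in (-1, 1)")


def _prolate_3ds(aspect: float) -> float:
    """3DS (%) of a prolate spheroid with long/short semiaxis ratio ``aspect``."""
    if aspect == 1.0:
        return 100.0
    b = 1.0
    a = aspect
    e = np.sqrt(1.0 - (b / a) ** 2)
    area = 2.0 * np.pi * b ** 2 * (1.0 + (a / (b * e)) * np.arcsin(e))
    vol = 4.0 * np.pi * a * b ** 2 / 3.0
    return 100.0 * np.pi ** (1 / 3) * (6.0 * vol) ** (2 / 3) / area


def _aspect_for_3ds(target_pct: float) -> float:
    """Invert the prolate-spheroid 3DS formula for the aspect ratio."""
    if target_pct >= 100.0:
        return 1.0
    return float(brentq(lambda r: _prolate_3ds(r) - target_pct, 1.0 + 1e-9, 20.0,
                        xtol=1e-10))


def make_cohort(spec: CohortSpec) -> dict:
    """Demo cohort: per-subject phantom + landmark artifacts and a summary table.

    Each subject gets a prolate-spheroid phantom whose aspect ratio is set
    from the drawn sphericity target and whose size is rescaled so the
    *measured* mesh volume equals the drawn maximum volume, plus a
    landmark set constructed to the drawn ED/ES/rotation angles.  All
    reported measurements are then re-derived by running the measurement
    pipeline on those artifacts (mesh volumetry and sphericity, landmark
    angle recovery, biplane sampling along an axis tilted by the subject's
    own ED deviation angle — which reproduces the foreshortening-driven
    negative bias of ventricle-oriented biplane volumes).

    Returns ``{"table": DataFrame, "phantoms": [...], "landmarks": [...],
    "spec": CohortSpec}``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    # shared latent factor couples ED angle and (indexed) max volume
    r = spec.angle_volume_r
    z_vol = rng.standard_normal(n)
    z_ang = r * z_vol + np.sqrt(1.0 - r * r) * rng.standard_normal(n)

    vmax = spec.max_lav_ml[0] + spec.max_lav_ml[1] * z_vol
    vmax = np.clip(vmax, 20.0, None)
    z_min = spec.minmax_corr * z_vol + np.sqrt(1 - spec.minmax_corr ** 2) \
        * rng.standard_normal(n)
    vmin = np.clip(spec.min_lav_ml[0] + spec.min_lav_ml[1] * z_min, 5.0, None)
    vmin = np.minimum(vmin, 0.95 * vmax)

    ed = np.clip(spec.ed_angle_deg[0] + spec.ed_angle_deg[1] * z_ang, 1.0, 80.0)
    cyc = spec.cyclic_angle_deg[0] + spec.cyclic_angle_deg[1] * rng.standard_normal(n)
    es = np.clip(ed - cyc, 0.5, 85.0)
    rot = np.abs(rng.normal(spec.rotation_deg[0], spec.rotation_deg[1], size=n))
    rot = np.clip(rot, 0.0, 90.0)
    s3ds = np.clip(rng.normal(spec.three_ds_pct[0], spec.three_ds_pct[1], size=n),
                   60.0, 99.5)

    weight = np.clip(rng.normal(*spec.weight_kg, size=n), 40.0, None)
    height = np.clip(rng.normal(*spec.height_cm, size=n), 140.0, None)
    sex = np.array(["female", "male"] * ((n + 1) // 2))[:n]

    rows = []
    phantoms = []
    landmark_sets = []
    for i in range(n):
        aspect = _aspect_for_3ds(float(s3ds[i]))
        b = (3.0 * vmax[i] * 1000.0 / (4.0 * np.pi * aspect)) ** (1.0 / 3.0)
        ph = PhantomSpec(semiaxes=(aspect * b, b, b),
                         subdivisions=spec.subdivisions,
                         seed=int(rng.integers(0, 2 ** 31 - 1)))
        mesh = make_phantom(ph)
        # rescale so the *measured* mesh volume hits the drawn target
        scale = (vmax[i] / mesh_volume(mesh)) ** (1.0 / 3.0)
        mesh = TriMesh(mesh.vertices * scale, mesh.faces)
        shape = lasp(mesh)

        lms = make_landmarks(theta=float(ed[i]), phi=float(min(rot[i], 90.0)),
                             theta_es=float(es[i]))
        angles = analyze_landmarks(lms)

        # ventricle-oriented biplane sampling: axis tilted off the phantom's
        # long axis (x) by the subject's own ED deviation angle, pivoting at
        # the mitral end of the chamber
        bp = lv_oriented_biplane(
            mesh, [1.0, 0.0, 0.0],
            tilt_deg=angles.la_lv_angle_ed,
            azimuth_deg=float(rng.uniform(0.0, 360.0)),
            rotation_offset=float(rng.uniform(0.0, 180.0)),
        )
        v_al_lv = biplane_volume(bp)

        bsa = body_surface_area(float(weight[i]), float(height[i]))
        rows.append({
            "subject_id": i + 1,
            "sex": sex[i],
            "weight_kg": float(weight[i]),
            "height_cm": float(height[i]),
            "bsa_m2": bsa,
            "max_lav_sax_ml": shape.volume,
            "min_lav_sax_ml": float(vmin[i]),
            "max_lav_sax_ml_m2": index_volume(shape.volume, bsa),
            "max_lav_al_lv_ml": v_al_lv,
            "al_lv_error_ml": v_al_lv - shape.volume,
            "ed_angle_deg": angles.la_lv_angle_ed,
            "es_angle_deg": angles.la_lv_angle_es,
            "cyclic_angle_deg": angles.cyclic_angle_change,
            "rotation_deg": angles.la_rotation_angle,
            "three_ds_pct": shape.three_ds,
            "lasp_pct": shape.lasp,
        })
        phantoms.append(ph)
        landmark_sets.append(lms)

    return {
        "table": pd.DataFrame(rows),
        "phantoms": phantoms,
        "landmarks": landmark_sets,
        "spec": spec,
    }
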