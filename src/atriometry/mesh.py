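"""Triangle-mesh geometry for cardiac chamber surfaces.

The left atrium (LA), segmented from short-axis cine MRI, is represented as
a closed triangle mesh.  This module computes the quantities the shape
analysis needs from that mesh: enclosed volume, surface area, surface
center of mass, planar cross-sections, and two sphericity indices.

Sphericity indices
------------------
``3DS``
    Ratio of the surface area of the sphere with the same volume as the
    chamber to the chamber's actual surface area, expressed in percent:

        3DS = 100 * pi^(1/3) * (6 V)^(2/3) / A

    By the isoperimetric inequality 3DS <= 100 for any closed surface, with
    equality only for the sphere.

``LASP``
    Best-fit-sphere sphericity.  A sphere is fitted with its center at the
    surface center of mass and radius equal to the area-weighted average
    distance AR from that center to the triangle centroids.  The
    area-weighted coefficient of variation of those distances (CVS)
    measures departure from the fitted sphere, and

        LASP = (1 - CVS) * 100.

    Because LASP penalizes the root of summed squared radial deviations it
    sits below 3DS on anisotropic chambers.

The "radius of a triangle" entering AR is the distance from the center of
mass to the triangle *centroid*; the center of mass itself is the
area-weighted surface centroid.  Both conventions are fixed constants of
the method (see docs/methods.md).

Units: coordinates in mm, areas in mm^2, volumes reported in mL (mm^3/1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriMesh",
    "PlaneSection",
    "SphericityResult",
    "mesh_volume",
    "mesh_surface_area",
    "center_of_mass",
    "sphericity_3ds",
    "lasp",
    "sphericity",
    "plane_section",
    "load_mesh",
    "save_mesh",
]

#: Relative area (w.r.t. the mean face area) below which a face counts as
#: degenerate and the mesh is rejected.
DEGENERATE_AREA_RTOL = 1e-12


class MeshError(ValueError):
    """Raised when a mesh violates a geometric contract."""


@dataclass(frozen=True)
class TriMesh:
    """A triangulated chamber surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Vertex indices, counter-clockwise when viewed from outside.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshError(f"faces must be (m, 3), got {f.shape}")
        if len(f) == 0:
            raise MeshError("mesh has no faces")
        if not np.isfinite(v).all():
            raise MeshError("vertices contain non-finite coordinates")
        if f.min() < 0 or f.max() >= len(v):
            raise MeshError(
                f"face index out of range: indices span [{f.min()}, {f.max()}] "
                f"but mesh has {len(v)} vertices"
            )
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        areas = self._face_areas()
        mean_area = areas.mean()
        if mean_area > 0 and (areas < DEGENERATE_AREA_RTOL * mean_area).any():
            n_bad = int((areas < DEGENERATE_AREA_RTOL * mean_area).sum())
            raise MeshError(f"mesh contains {n_bad} degenerate (zero-area) faces")

    # -- basic derived quantities ------------------------------------------

    def _face_corners(self):
        v = self.vertices
        f = self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def _face_areas(self) -> np.ndarray:
        a, b, c = self._face_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def _face_centroids(self) -> np.ndarray:
        a, b, c = self._face_corners()
        return (a + b + c) / 3.0

    def open_edge_count(self) -> int:
        """Number of directed edges whose reverse is missing.

        Zero for a watertight, consistently oriented mesh: every undirected
        edge must be traversed exactly once in each direction.
        """
        f = self.faces
        directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        fwd = {(int(a), int(b)) for a, b in directed}
        if len(fwd) != len(directed):
            # duplicated directed edge: inconsistent winding or doubled face
            return len(directed) - len(fwd) + sum(
                1 for a, b in fwd if (b, a) not in fwd
            )
        return sum(1 for a, b in fwd if (b, a) not in fwd)

    @property
    def is_watertight(self) -> bool:
        return self.open_edge_count() == 0

    def require_watertight(self, operation: str) -> None:
        n_open = self.open_edge_count()
        if n_open:
            raise MeshError(
                f"{operation} requires a watertight mesh, but {n_open} "
                f"edge(s) are open or inconsistently wound; clinical meshes "
                f"with mitral/vein openings must be capped upstream"
            )

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, m: _trimesh.Trimesh) -> "TriMesh":
        return cls(np.asarray(m.vertices, float), np.asarray(m.faces, np.int64))

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "TriMesh":
        """Apply a rigid motion (rotation matrix then translation)."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, float).T
        if translation is not None:
            v = v + np.asarray(translation, float)
        return TriMesh(v, self.faces)


@dataclass(frozen=True)
class PlaneSection:
    """Cross-section of a mesh by a plane.

    ``polygons`` are closed 2D loops expressed in the plane's own
    coordinate frame; ``area`` is the enclosed area (holes subtracted);
    ``max_chord`` is the extent of the section along ``axis_in_plane``.
    An empty section (plane misses the mesh) has area 0 and max_chord 0.
    """

    plane_origin: np.ndarray
    plane_normal: np.ndarray
    polygons: list = field(default_factory=list)
    area: float = 0.0
    max_chord: float = 0.0

    @property
    def is_empty(self) -> bool:
        return self.area == 0.0 and not self.polygons


@dataclass(frozen=True)
class SphericityResult:
    """Shape metrics of a closed chamber surface.

    volume (mL), surface_area (mm^2), three_ds (%), com (mm), ar (mm),
    cvs (dimensionless fraction), lasp (%).
    """

    volume: float
    surface_area: float
    three_ds: float
    com: np.ndarray
    ar: float
    cvs: float
    lasp: float


# ---------------------------------------------------------------------------
# operations


def mesh_volume(mesh: TriMesh) -> float:
    """Enclosed volume in mL via the divergence theorem.

    The signed tetrahedron volumes v0 . (v1 x v2) / 6 are summed over the
    faces; the absolute value is returned so either consistent global
    orientation is accepted.  Requires a watertight mesh.
    """
    mesh.require_watertight("volume computation")
    a, b, c = mesh._face_corners()
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    return abs(signed) / 1000.0


def mesh_surface_area(mesh: TriMesh) -> float:
    """Total surface area in mm^2 (sum of triangle areas)."""
    return float(mesh._face_areas().sum())


def center_of_mass(mesh: TriMesh) -> np.ndarray:
    """Area-weighted surface centroid (mm)."""
    w = mesh._face_areas()
    total = w.sum()
    if total <= 0:
        raise MeshError("mesh has zero total surface area")
    return (w[:, None] * mesh._face_centroids()).sum(axis=0) / total


def sphericity_3ds(volume_ml: float, surface_area_mm2: float) -> float:
    """3D sphericity index (percent).

    100 * pi^(1/3) * (6 V)^(2/3) / A with V in mm^3 — the surface area of
    the equal-volume sphere over the actual surface area.
    """
    if volume_ml <= 0 or surface_area_mm2 <= 0:
        raise ValueError(
            f"volume and surface area must be positive, got "
            f"{volume_ml} mL and {surface_area_mm2} mm^2"
        )
    v_mm3 = volume_ml * 1000.0
    return 100.0 * np.pi ** (1 / 3) * (6.0 * v_mm3) ** (2 / 3) / surface_area_mm2


def lasp(mesh: TriMesh) -> SphericityResult:
    """Best-fit-sphere sphericity (LASP) together with 3DS.

    Per-triangle radius = distance from the surface center of mass to the
    triangle centroid; AR = area-weighted mean radius; CVS = area-weighted
    SD of the radii divided by AR; LASP = (1 - CVS) * 100.
    """
    mesh.require_watertight("sphericity computation")
    com = center_of_mass(mesh)
    w = mesh._face_areas()
    radii = np.linalg.norm(mesh._face_centroids() - com, axis=1)
    wsum = w.sum()
    ar = float((w * radii).sum() / wsum)
    if ar <= 0:
        raise MeshError("average radius is zero; degenerate mesh")
    var = float((w * (radii - ar) ** 2).sum() / wsum)
    cvs = np.sqrt(var) / ar
    vol = mesh_volume(mesh)
    area = mesh_surface_area(mesh)
    return SphericityResult(
        volume=vol,
        surface_area=area,
        three_ds=sphericity_3ds(vol, area),
        com=com,
        ar=ar,
        cvs=float(cvs),
        lasp=float((1.0 - cvs) * 100.0),
    )


# alias: full shape report from a mesh
sphericity = lasp


def plane_section(
    mesh: TriMesh,
    plane_origin,
    plane_normal,
    axis_in_plane,
) -> PlaneSection:
    """Cross-section of a watertight mesh by a plane.

    Parameters
    ----------
    plane_origin, plane_normal : 3-vectors (mm; normal need not be unit).
    axis_in_plane : 3-vector orthogonal to the normal; the chord length of
        the section is measured along this direction.

    Returns an empty :class:`PlaneSection` when the plane misses the mesh.
    """
    origin = np.asarray(plane_origin, float)
    normal = np.asarray(plane_normal, float)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise ValueError("plane normal must be non-zero")
    normal = normal / nn
    axis = np.asarray(axis_in_plane, float)
    an = np.linalg.norm(axis)
    if an == 0:
        raise ValueError("axis_in_plane must be non-zero")
    axis = axis / an
    if abs(axis @ normal) > 1e-8:
        raise ValueError("axis_in_plane must be orthogonal to the plane normal")
    mesh.require_watertight("plane sectioning")

    path3d = mesh.to_trimesh().section(plane_origin=origin, plane_normal=normal)
    if path3d is None or len(path3d.vertices) == 0:
        return PlaneSection(plane_origin=origin, plane_normal=normal)

    path2d, _ = path3d.to_2D()
    polys = list(path2d.polygons_full)
    area = float(sum(p.area for p in polys))
    proj = np.asarray(path3d.vertices, float) @ axis
    max_chord = float(proj.max() - proj.min()) if len(proj) else 0.0
    loops = [np.asarray(p.exterior.coords, float) for p in polys]
    return PlaneSection(
        plane_origin=origin,
        plane_normal=normal,
        polygons=loops,
        area=area,
        max_chord=max_chord,
    )


# ---------------------------------------------------------------------------
# mesh file I/O (PLY / STL / OFF)


def load_mesh(path) -> TriMesh:
    """Load a triangle mesh (PLY, STL, or OFF) and normalize to TriMesh."""
    m = _trimesh.load_mesh(str(path), process=False)
    if isinstance(m, _trimesh.Scene):
        geoms = list(m.geometry.values())
        if len(geoms) != 1:
            raise MeshError(f"expected a single mesh in {path}, found {len(geoms)}")
        m = geoms[0]
    return TriMesh.from_trimesh(m)


def save_mesh(mesh: TriMesh, path) -> None:
    """Write a mesh in the format implied by the file extension.

    PLY and STL are written as ASCII; OFF is ASCII by definition.
    """
    path = Path(path)
    tm = mesh.to_trimesh()
    suffix = path.suffix.lower()
    if suffix == ".ply":
        data = tm.export(file_type="ply", encoding="ascii")
    elif suffix in {".stl", ".off"}:
        data = tm.export(file_type=suffix[1:])
        if suffix == ".stl":
            data = tm.export(file_type="stl_ascii")
    else:
        raise ValueError(f"unsupported mesh format: {suffix}")
    if isinstance(data, bytes):
        path.write_bytes(data)
    else:
        path.write_text(data)
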