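"""Mesh geometry: volume, area, center of mass, sections, sphericity."""

import numpy as np
import pytest
from scipy import integrate

from atriometry import (
    MeshError,
    PhantomSpec,
    TriMesh,
    center_of_mass,
    lasp,
    make_phantom,
    mesh_surface_area,
    mesh_volume,
    plane_section,
    sphericity_3ds,
)
from conftest import random_rotation


def ellipsoid_area_quadrature(a, b, c):
    """Numerical-quadrature oracle for the ellipsoid surface area."""

    def integrand(theta, phi):
        st, ct = np.sin(theta), np.cos(theta)
        sp, cp = np.sin(phi), np.cos(phi)
        # |r_theta x r_phi| for r = (a st cp, b st sp, c ct)
        return st * np.sqrt(
            (b * c * st * cp) ** 2 + (a * c * st * sp) ** 2 + (a * b * ct) ** 2
        )

    val, _ = integrate.dblquad(integrand, 0, 2 * np.pi, 0, np.pi,
                               epsabs=1e-10, epsrel=1e-10)
    return val


class TestVolumeAndArea:
    def test_unit_cube(self, unit_cube):
        assert mesh_volume(unit_cube) == pytest.approx(0.001, rel=1e-12)
        assert mesh_surface_area(unit_cube) == pytest.approx(6.0, rel=1e-12)

    def test_icosphere_converges_to_sphere(self, sphere_r10):
        assert mesh_volume(sphere_r10) == pytest.approx(4.18879, rel=5e-3)
        assert mesh_surface_area(sphere_r10) == pytest.approx(1256.64, rel=5e-3)

    def test_rigid_motion_invariance(self, sphere_r10):
        rng = np.random.default_rng(7)
        moved = sphere_r10.transformed(rotation=random_rotation(rng),
                                       translation=[100.0, -50.0, 3.0])
        assert mesh_volume(moved) == pytest.approx(mesh_volume(sphere_r10),
                                                   rel=1e-9)
        assert mesh_surface_area(moved) == pytest.approx(
            mesh_surface_area(sphere_r10), rel=1e-9)

    def test_winding_flip_same_volume(self, sphere_r10):
        flipped = TriMesh(sphere_r10.vertices, sphere_r10.faces[:, ::-1])
        assert mesh_volume(flipped) == pytest.approx(mesh_volume(sphere_r10),
                                                     rel=1e-12)

    def test_ellipsoid_area_matches_quadrature(self, spheroid_20_10_10):
        oracle = ellipsoid_area_quadrature(20, 10, 10)
        assert mesh_surface_area(spheroid_20_10_10) == pytest.approx(
            oracle, rel=5e-3)

    def test_volume_matches_monte_carlo(self):
        """Divergence-theorem volume agrees with point-in-mesh sampling.

        The oracle casts +z rays and counts triangle crossings (parity test),
        touching none of the volume code under test.
        """
        from atriometry import PhantomSpec, make_phantom

        m = make_phantom(PhantomSpec(semiaxes=(20, 15, 10), subdivisions=3,
                                     bump_amplitude=0.15, bump_count=5, seed=8))
        v, f = m.vertices, m.faces
        p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        rng = np.random.default_rng(11)
        lo = v.min(0) - 0.5
        hi = v.max(0) + 0.5
        n = 8000
        pts = rng.uniform(lo, hi, size=(n, 3))

        # 2D barycentric pre-computation in the xy projection
        d = (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1]) \
            - (p2[:, 0] - p0[:, 0]) * (p1[:, 1] - p0[:, 1])
        ok = np.abs(d) > 1e-14
        inside = np.zeros(n, bool)
        for i, (px, py, pz) in enumerate(pts):
            wa = ((p1[:, 0] - px) * (p2[:, 1] - py)
                  - (p2[:, 0] - px) * (p1[:, 1] - py)) / np.where(ok, d, 1.0)
            wb = ((p2[:, 0] - px) * (p0[:, 1] - py)
                  - (p0[:, 0] - px) * (p2[:, 1] - py)) / np.where(ok, d, 1.0)
            wc = 1.0 - wa - wb
            hit = ok & (wa >= 0) & (wb >= 0) & (wc >= 0)
            z = wa * p0[:, 2] + wb * p1[:, 2] + wc * p2[:, 2]
            crossings = int(np.count_nonzero(hit & (z > pz)))
            inside[i] = crossings % 2 == 1

        box = float(np.prod(hi - lo))
        p = inside.mean()
        est = p * box / 1000.0
        se = box * np.sqrt(p * (1 - p) / n) / 1000.0
        assert abs(est - mesh_volume(m)) < 3 * se

    def test_non_watertight_raises_with_open_edges(self, sphere_r10):
        holed = TriMesh(sphere_r10.vertices, sphere_r10.faces[:-1])
        with pytest.raises(MeshError, match=r"3 edge"):
            mesh_volume(holed)

    def test_degenerate_face_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        faces = np.array([[0, 1, 2], [0, 1, 3], [1, 2, 3], [0, 3, 2],
                          [0, 0, 1]])
        with pytest.raises(MeshError, match="degenerate"):
            TriMesh(verts, faces)

    def test_bad_face_index_rejected(self):
        with pytest.raises(MeshError, match="out of range"):
            TriMesh(np.eye(3), np.array([[0, 1, 5]]))


class TestCenterOfMass:
    def test_sphere_at_origin(self, sphere_r10):
        assert np.allclose(center_of_mass(sphere_r10), 0.0, atol=1e-9)

    def test_translation_equivariance(self, ellipsoid_20_15_10):
        t = np.array([3.0, -8.0, 12.5])
        com0 = center_of_mass(ellipsoid_20_15_10)
        com1 = center_of_mass(ellipsoid_20_15_10.transformed(translation=t))
        assert np.allclose(com1, com0 + t, atol=1e-9)

    def test_single_triangle_is_centroid(self):
        verts = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0]], float)
        m = TriMesh(verts, np.array([[0, 1, 2]]))
        assert np.allclose(center_of_mass(m), [1.0, 1.0, 0.0])


class TestSphericity3DS:
    def test_sphere_attains_100(self):
        for r in (1.0, 10.0, 37.2):
            v = 4 * np.pi * r ** 3 / 3 / 1000.0
            a = 4 * np.pi * r ** 2
            assert sphericity_3ds(v, a) == pytest.approx(100.0, rel=1e-12)

    def test_cube_value(self):
        # pi^(1/3) * 6^(2/3) / 6 = 0.80600
        assert sphericity_3ds(0.001, 6.0) == pytest.approx(80.60, abs=0.005)

    def test_matches_quadrature_oracle_on_spheroid(self, spheroid_20_10_10):
        area = ellipsoid_area_quadrature(20, 10, 10)
        vol = 4 * np.pi * 20 * 10 * 10 / 3 / 1000.0
        expected = sphericity_3ds(vol, area)
        measured = lasp(spheroid_20_10_10).three_ds
        assert measured == pytest.approx(expected, abs=0.2)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            sphericity_3ds(0.0, 6.0)
        with pytest.raises(ValueError):
            sphericity_3ds(1.0, -1.0)


class TestLASP:
    def test_sphere_approaches_100(self, sphere_r10):
        assert lasp(sphere_r10).lasp > 99.5

    def test_matches_brute_force_oracle(self, spheroid_20_10_10):
        """Area-weighted radius statistics recomputed by a naive loop."""
        m = spheroid_20_10_10
        v, f = m.vertices, m.faces
        areas, cents = [], []
        for i0, i1, i2 in f:
            p0, p1, p2 = v[i0], v[i1], v[i2]
            areas.append(0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0)))
            cents.append((p0 + p1 + p2) / 3.0)
        areas = np.array(areas)
        cents = np.array(cents)
        com = (areas[:, None] * cents).sum(0) / areas.sum()
        radii = np.linalg.norm(cents - com, axis=1)
        ar = (areas * radii).sum() / areas.sum()
        cvs = np.sqrt((areas * (radii - ar) ** 2).sum() / areas.sum()) / ar
        expected = (1 - cvs) * 100.0

        r = lasp(m)
        assert r.lasp == pytest.approx(expected, abs=1e-6)
        assert r.ar == pytest.approx(ar, abs=1e-9)

    def test_scale_invariance(self, ellipsoid_20_15_10):
        m = ellipsoid_20_15_10
        scaled = TriMesh(m.vertices * 3.0, m.faces)
        r0, r1 = lasp(m), lasp(scaled)
        assert r1.lasp == pytest.approx(r0.lasp, rel=1e-9, abs=1e-9)
        assert r1.three_ds == pytest.approx(r0.three_ds, rel=1e-9)

    def test_rigid_motion_invariance(self, ellipsoid_20_15_10):
        rng = np.random.default_rng(3)
        moved = ellipsoid_20_15_10.transformed(
            rotation=random_rotation(rng), translation=[5.0, 6.0, -7.0])
        r0, r1 = lasp(ellipsoid_20_15_10), lasp(moved)
        assert r1.lasp == pytest.approx(r0.lasp, abs=1e-9)
        assert r1.three_ds == pytest.approx(r0.three_ds, abs=1e-9)


class TestShapeOrdering:
    def test_indices_decrease_with_aspect_ratio(self):
        """Elongating a spheroid strictly lowers both sphericity indices."""
        aspects = [1.0, 1.5, 2.0, 2.5, 3.0]
        vals = []
        for a in aspects:
            m = make_phantom(PhantomSpec(semiaxes=(10 * a, 10, 10),
                                         subdivisions=3))
            r = lasp(m)
            vals.append((r.three_ds, r.lasp))
        tds = [v[0] for v in vals]
        lsp = [v[1] for v in vals]
        assert all(x > y for x, y in zip(tds, tds[1:]))
        assert all(x > y for x, y in zip(lsp, lsp[1:]))

    def test_lasp_below_3ds_on_anisotropic_phantoms(self):
        """The best-fit-sphere index penalizes anisotropy more than 3DS."""
        for aspect in (1.2, 1.5, 2.0, 3.0):
            m = make_phantom(PhantomSpec(semiaxes=(10 * aspect, 10, 10),
                                         subdivisions=3))
            r = lasp(m)
            assert r.lasp < r.three_ds


class TestPlaneSection:
    def test_sphere_equator(self, sphere_r10):
        s = plane_section(sphere_r10, [0, 0, 0], [0, 0, 1], [1, 0, 0])
        assert s.area == pytest.approx(np.pi * 100, rel=0.01)
        assert s.max_chord == pytest.approx(20.0, rel=0.01)

    def test_sphere_offset_cut(self, sphere_r10):
        s = plane_section(sphere_r10, [0, 0, 6], [0, 0, 1], [1, 0, 0])
        assert s.area == pytest.approx(np.pi * 64, rel=0.01)

    def test_plane_misses_mesh(self, sphere_r10):
        s = plane_section(sphere_r10, [0, 0, 20], [0, 0, 1], [1, 0, 0])
        assert s.is_empty
        assert s.area == 0.0
        assert s.max_chord == 0.0

    def test_axis_must_be_in_plane(self, sphere_r10):
        with pytest.raises(ValueError, match="orthogonal"):
            plane_section(sphere_r10, [0, 0, 0], [0, 0, 1], [0, 0, 1])
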