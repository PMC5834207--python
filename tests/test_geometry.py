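"""Cell-surface geometry: shape generation and nearest-point queries."""

import math

import numpy as np
import pytest
import trimesh

from cmtsim.geometry import (CellSurface, InvalidShapeError, ShapeSpec,
                             brute_force_nearest, build_ellipsoid,
                             build_rounded_box, build_shape, load_mesh,
                             nearest_surface, standard_shape_spec,
                             sample_surface_point, save_mesh, surface_area,
                             tangent_plane, STANDARD_SHAPES)


def knud_thomsen_area(a, b, c, p=1.6075):
    """Approximate ellipsoid surface area (relative error < 1.06%)."""
    return 4 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p)
                          / 3) ** (1 / p)


def ellipsoid_area_quadrature(a, b, c, n=400):
    """Numeric-quadrature oracle for the ellipsoid surface area."""
    th = np.linspace(0, math.pi, n)[:, None]      # polar
    ph = np.linspace(0, 2 * math.pi, 2 * n)[None, :]
    st, ct = np.sin(th), np.cos(th)
    sp, cp = np.sin(ph), np.cos(ph)
    # |r_theta x r_phi| for x=a st cp, y=b st sp, z=c ct
    E = np.sqrt((b * c * st ** 2 * cp) ** 2 + (a * c * st ** 2 * sp) ** 2
                + (a * b * st * ct) ** 2)
    return float(np.trapezoid(np.trapezoid(E, ph[0], axis=1), th[:, 0]))


class TestRoundedBox:
    @pytest.mark.parametrize("name,dims", [("cube", (8.8, 8.8, 8.8)),
                                           ("long", (4.8, 4.8, 15.6)),
                                           ("square", (9.0, 9.0, 4.7))])
    def test_sharp_shapes_match_dimensions(self, name, dims):
        mesh = build_shape(standard_shape_spec(name, "sharp"))
        assert mesh.is_watertight
        extents = mesh.bounds[1] - mesh.bounds[0]
        assert np.allclose(extents, dims, atol=0.45)  # within one edge length
        if name == "long":
            assert np.argmax(extents) == 2
        if name == "cube":
            diag = np.linalg.norm(mesh.bounds[1] - mesh.bounds[0])
            assert diag == pytest.approx(8.8 * math.sqrt(3), rel=0.05)

    def test_full_radius_gives_sphere(self):
        spec = ShapeSpec("rounded_box", (6.0, 6.0, 6.0), corner_radius=3.0,
                         mesh_resolution=0.4)
        mesh = build_rounded_box(spec)
        r = np.linalg.norm(mesh.vertices - mesh.vertices.mean(axis=0), axis=1)
        assert np.all(np.abs(r - 3.0) < 0.02 * 3.0)

    def test_excessive_radius_rejected(self):
        with pytest.raises(InvalidShapeError):
            ShapeSpec("rounded_box", (6.0, 6.0, 6.0), corner_radius=3.5)

    def test_unsmoothed_cube_area(self):
        spec = ShapeSpec("rounded_box", (8.8, 8.8, 8.8), corner_radius=0.0)
        assert surface_area(build_rounded_box(spec)) == pytest.approx(
            6 * 8.8 ** 2, rel=1e-6)

    def test_smoothing_reduces_area(self):
        sharp = build_rounded_box(ShapeSpec("rounded_box", (8.8, 8.8, 8.8),
                                            corner_radius=0.0))
        smooth = build_rounded_box(ShapeSpec("rounded_box", (8.8, 8.8, 8.8),
                                             corner_radius=1.3))
        assert surface_area(smooth) < surface_area(sharp)

    def test_resolution_convergence(self):
        areas = [surface_area(build_rounded_box(
            ShapeSpec("rounded_box", (8.8, 8.8, 8.8), corner_radius=1.3,
                      mesh_resolution=res))) for res in (0.4, 0.2)]
        assert abs(areas[1] - areas[0]) / areas[0] < 0.01


class TestEllipsoid:
    def test_standard_ellipsoid(self):
        mesh = build_shape(standard_shape_spec("ellipsoid"))
        assert mesh.is_watertight
        extents = mesh.bounds[1] - mesh.bounds[0]
        assert np.allclose(extents, (10.3, 10.3, 16.8), rtol=0.01)

    def test_equal_axes_is_sphere(self):
        mesh = build_ellipsoid(ShapeSpec("ellipsoid", (8.0, 8.0, 8.0)))
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert np.allclose(r, 4.0, rtol=1e-6)

    def test_area_matches_quadrature_oracle(self):
        mesh = build_shape(standard_shape_spec("ellipsoid"))
        a = b = 10.3 / 2
        c = 16.8 / 2
        oracle = ellipsoid_area_quadrature(a, b, c)
        assert surface_area(mesh) == pytest.approx(oracle, rel=0.02)
        assert oracle == pytest.approx(knud_thomsen_area(a, b, c), rel=0.011)

    def test_non_revolution_rejected(self):
        with pytest.raises(InvalidShapeError):
            ShapeSpec("ellipsoid", (6.0, 8.0, 10.0))


class TestNearestSurface:
    def test_centroid_of_ellipsoid(self, ellipsoid_surface):
        probe = ellipsoid_surface.probe([0.0, 0.0, 0.0])
        # nearest surface point from the center sits on the short axis
        assert probe.distance == pytest.approx(10.3 / 2, rel=0.01)
        assert probe.inside

    def test_sphere_interior_distance(self, coarse_sphere_surface):
        probe = coarse_sphere_surface.probe([1.0, 0.0, 0.0])
        assert probe.distance == pytest.approx(2.0, abs=0.02)

    def test_outside_point_flagged(self, cube_surface):
        probe = cube_surface.probe([0.0, 0.0, 10.0])
        assert not probe.inside
        assert probe.distance == pytest.approx(10.0 - 4.4, abs=0.01)

    def test_matches_brute_force(self, cube_surface, rng):
        pts = rng.uniform(-4.4, 4.4, size=(300, 3))
        _, _, dist, _ = cube_surface.probe_points(pts)
        oracle = brute_force_nearest(cube_surface.mesh, pts)
        assert np.allclose(dist, oracle, atol=1e-9)

    def test_matches_brute_force_ellipsoid(self, ellipsoid_surface, rng):
        pts = rng.uniform(-5, 5, size=(200, 3)) * np.array([1, 1, 1.6])
        _, _, dist, _ = ellipsoid_surface.probe_points(pts)
        oracle = brute_force_nearest(ellipsoid_surface.mesh, pts)
        assert np.allclose(dist, oracle, atol=1e-9)

    def test_containment_bounds(self, cube_surface):
        assert cube_surface.contains(np.zeros((1, 3)))[0]
        assert not cube_surface.contains(np.array([[0.0, 0.0, 20.0]]))[0]


class TestTangentPlane:
    def test_top_face_normal(self, cube_surface):
        probe = cube_surface.probe([0.3, -0.2, 4.0])
        point, normal = tangent_plane(probe)
        assert np.allclose(normal, [0, 0, 1], atol=1e-6)
        assert np.allclose(point[:2], [0.3, -0.2], atol=1e-6)

    def test_tangential_vectors_orthogonal(self, cube_surface, rng):
        probe = cube_surface.probe([0.3, -0.2, 4.0])
        _, normal = tangent_plane(probe)
        t = np.cross(normal, rng.normal(size=3))
        t /= np.linalg.norm(t)
        assert abs(t @ normal) < 1e-12

    def test_sphere_normal_is_radial(self, coarse_sphere_surface):
        p = np.array([1.5, 1.0, 0.5])
        probe = coarse_sphere_surface.probe(p)
        radial = p / np.linalg.norm(p)
        assert probe.normal @ radial > 0.99


class TestSurfaceSampling:
    def test_area_weighted_counts(self, rng):
        # plain cube: per-face counts must follow face areas (binomial 3-sigma)
        spec = ShapeSpec("rounded_box", (4.0, 4.0, 8.0), corner_radius=0.0,
                         mesh_resolution=1.0)
        surface = CellSurface(build_shape(spec))
        n = 10_000
        pos, _ = surface.sample(n, rng)
        total = surface.area
        for axis, half in ((0, 2.0), (1, 2.0), (2, 4.0)):
            face_area = {0: 32.0, 1: 32.0, 2: 16.0}[axis]
            for sgn in (1, -1):
                hits = int(np.sum(np.abs(pos[:, axis] - sgn * half) < 1e-9))
                p = face_area / total
                sigma = math.sqrt(n * p * (1 - p))
                assert abs(hits - n * p) < 3.5 * sigma

    def test_points_lie_on_surface(self, cube_surface, rng):
        pos, _ = cube_surface.sample(500, rng)
        assert np.all(cube_surface.distances(pos) < 1e-9)

    def test_fixed_seed_reproducible(self, cube_surface):
        a, _ = cube_surface.sample(100, np.random.default_rng(7))
        b, _ = cube_surface.sample(100, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_single_point_helper(self, cube_surface, rng):
        pos, normal = sample_surface_point(cube_surface, rng)
        assert np.linalg.norm(normal) == pytest.approx(1.0, abs=1e-9)
        assert cube_surface.probe(pos).distance < 1e-9


class TestMeshIO:
    @pytest.mark.parametrize("ext", ["ply", "obj"])
    def test_roundtrip_preserves_geometry(self, tmp_path, ext):
        mesh = build_shape(standard_shape_spec("cube", "sharp"))
        path = tmp_path / f"cube.{ext}"
        save_mesh(mesh, path)
        back = load_mesh(path)
        assert surface_area(back) == pytest.approx(surface_area(mesh),
                                                   rel=1e-5)
        assert back.is_watertight

    def test_normals_survive_ply(self, tmp_path):
        mesh = build_shape(standard_shape_spec("ellipsoid"))
        path = tmp_path / "ell.ply"
        save_mesh(mesh, path)
        back = load_mesh(path)
        surface = CellSurface(back)
        probe = surface.probe([0.0, 0.0, 8.0])
        assert probe.normal @ np.array([0, 0, 1.0]) > 0.99


class TestPaperShapeRegistry:
    def test_all_shapes_build_watertight(self):
        for name in list(STANDARD_SHAPES) + ["ellipsoid"]:
            for variant in ("sharp", "smooth"):
                mesh = build_shape(standard_shape_spec(name, variant))
                assert mesh.is_watertight
                assert surface_area(mesh) > 0

    def test_smooth_radius_capped_at_half_min_dimension(self):
        spec = standard_shape_spec("square", "smooth")
        assert spec.corner_radius == pytest.approx(4.7 / 2)
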