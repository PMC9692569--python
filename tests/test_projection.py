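"""Projection, convex hulls, silhouettes and rasterization."""

import numpy as np
import pytest
import shapely
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon, box

from flypose._fastgeom import add_convex_patch, convex_hull_ccw
from flypose.fly_model import PoseVector17, default_geometry
from flypose.projection import (CameraModel, clip_polygon_to_rect,
                                convex_hull_2d, coverage_convex,
                                polygon_area, project_points, rasterize,
                                rasterize_convex, rasterize_parts, silhouette)


def canonical_camera(w=64, h=64):
    return CameraModel(M=np.hstack([np.eye(3), np.zeros((3, 1))]),
                       image_width=w, image_height=h, label="canon")


class TestProjectPoints:
    def test_canonical_camera(self):
        pts = project_points([[0.2, 0.4, 2.0]], canonical_camera())
        assert np.allclose(pts, [[0.1, 0.2]])

    def test_scale_invariance_of_M(self, rng):
        M = rng.normal(size=(3, 4))
        cam1 = CameraModel(M=M, image_width=10, image_height=10)
        cam2 = CameraModel(M=3.7 * M, image_width=10, image_height=10)
        pts = rng.normal(size=(20, 3))
        assert np.allclose(project_points(pts, cam1),
                           project_points(pts, cam2))

    def test_matches_scalar_oracle(self, rng):
        M = rng.normal(size=(3, 4))
        cam = CameraModel(M=M, image_width=10, image_height=10)
        pts = rng.normal(size=(100, 3))
        out = project_points(pts, cam)
        for k, p in enumerate(pts):
            ip = M[0, 0] * p[0] + M[0, 1] * p[1] + M[0, 2] * p[2] + M[0, 3]
            jp = M[1, 0] * p[0] + M[1, 1] * p[1] + M[1, 2] * p[2] + M[1, 3]
            t = M[2, 0] * p[0] + M[2, 1] * p[1] + M[2, 2] * p[2] + M[2, 3]
            assert abs(out[k, 0] - ip / t) < 1e-10
            assert abs(out[k, 1] - jp / t) < 1e-10

    def test_point_at_infinity_reports_index(self):
        cam = canonical_camera()
        with pytest.raises(ValueError, match="point 1"):
            project_points([[0.1, 0.1, 1.0], [0.5, 0.5, 0.0]], cam)

    def test_rank_deficient_matrix_rejected(self):
        M = np.zeros((3, 4))
        M[0, 0] = M[1, 1] = 1.0
        with pytest.raises(ValueError, match="rank"):
            CameraModel(M=M, image_width=4, image_height=4)


class TestConvexHull:
    def test_square_with_interior_points(self, rng):
        corners = np.array([[0, 0], [4, 0], [4, 4], [0, 4.0]])
        interior = rng.uniform(0.5, 3.5, size=(30, 2))
        hull = convex_hull_2d(np.vstack([corners, interior]))
        assert len(hull) == 4
        assert set(map(tuple, hull)) == set(map(tuple, corners))

    def test_circle_keeps_all_points(self):
        ang = np.linspace(0, 2 * np.pi, 17, endpoint=False)
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        assert len(convex_hull_2d(pts)) == 17

    def test_ccw_orientation(self, rng):
        hull = convex_hull_2d(rng.normal(size=(50, 2)))
        assert polygon_area(hull) > 0

    def test_containment_oracle(self, rng):
        pts = rng.normal(size=(200, 2))
        hull = convex_hull_2d(pts)
        nxt = np.roll(hull, -1, axis=0)
        # every input point lies left of (or on) every CCW hull edge
        for p in pts:
            cross = ((nxt[:, 0] - hull[:, 0]) * (p[1] - hull[:, 1])
                     - (nxt[:, 1] - hull[:, 1]) * (p[0] - hull[:, 0]))
            assert (cross >= -1e-9).all()

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError):
            convex_hull_2d(pts)

    def test_fast_hull_matches_scipy(self, rng):
        for n in (10, 60, 300):
            pts = rng.normal(size=(n, 2)) * 10 + 100
            h_fast = convex_hull_ccw(pts)
            h_ref = pts[ConvexHull(pts).vertices]
            assert set(map(tuple, h_fast)) == set(map(tuple, h_ref))
            assert polygon_area(h_fast) == pytest.approx(
                polygon_area(h_ref), abs=1e-9)


class TestSilhouette:
    def test_union_area_bounds(self, geometry, cameras):
        pose = PoseVector17(phi_l=40, phi_r=-30, theta_l=10, psi_l=30,
                            psi_r=60, pitch=45)
        sil = silhouette(pose, geometry, cameras[0])
        part_areas = [Polygon(h).area for h in sil.part_hulls.values()]
        assert sil.area <= sum(part_areas) + 1e-9
        assert sil.area >= max(part_areas) - 1e-9
        # cross-check against the rasterized pixel count
        px = rasterize(sil, cameras[0]).sum()
        assert abs(px - sil.area) < 0.5 * sum(
            Polygon(h).length for h in sil.part_hulls.values())

    def test_disjoint_parts_add(self):
        # shrunken body plus far-apart hinges make the three hulls disjoint
        g = default_geometry()
        g.body_vertices = g.body_vertices * 0.05
        g.rest_hinge_left = np.array([0.0, 3.0, 0.0])
        g.rest_hinge_right = np.array([0.0, -3.0, 0.0])
        cam = CameraModel(
            M=np.array([[10.0, 0, 0, 96], [0, 10.0, 0, 96], [0, 0, 0, 1.0]]),
            image_width=192, image_height=192, label="ortho")
        sil = silhouette(PoseVector17(), g, cam)
        parts = [Polygon(h) for h in sil.part_hulls.values()]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not parts[i].intersects(parts[j])
        assert sil.area == pytest.approx(sum(p.area for p in parts), rel=1e-9)


class TestRasterize:
    def test_exact_pixel_block(self):
        cam = canonical_camera(16, 16)
        # rectangle covering pixel centres 3..7 x 5..9 exactly
        rect = np.array([[2.6, 4.6], [7.4, 4.6], [7.4, 9.4], [2.6, 9.4]])
        mask = rasterize(rect, cam)
        assert mask.sum() == 5 * 5
        assert mask[5:10, 3:8].all()

    def test_polygon_outside_image(self):
        cam = canonical_camera(16, 16)
        tri = np.array([[100, 100], [120, 100], [110, 120.0]])
        assert rasterize(tri, cam).sum() == 0

    def test_triangle_area_within_perimeter_band(self, rng):
        cam = canonical_camera(128, 128)
        for _ in range(10):
            tri = rng.uniform(10, 110, size=(3, 2))
            area = abs(polygon_area(tri))
            if area < 20:
                continue
            per = np.sum(np.linalg.norm(np.roll(tri, -1, 0) - tri, axis=1))
            count = rasterize(tri, cam).sum()
            assert abs(count - area) <= per

    def test_convex_fast_path_matches_shapely(self, rng):
        cam = canonical_camera(64, 64)
        for _ in range(10):
            hull = convex_hull_2d(rng.uniform(5, 58, size=(12, 2)))
            a = rasterize(hull, cam)
            b = rasterize_convex(hull, (64, 64))
            # identical except possibly exactly-on-edge pixel centres
            assert np.logical_xor(a, b).sum() <= 2

    def test_jit_patch_matches_reference(self, rng):
        for _ in range(10):
            hull = convex_hull_2d(rng.uniform(5, 58, size=(15, 2)))
            ref_bin = rasterize_convex(hull, (64, 64))
            buf = np.zeros((64, 64), dtype=np.float32)
            add_convex_patch(buf, hull[:, 0], hull[:, 1], 0, 0, False, 1.0)
            assert np.array_equal(buf > 0.5, ref_bin)
            ref_cov = coverage_convex(hull, (64, 64))
            buf = np.zeros((64, 64), dtype=np.float32)
            add_convex_patch(buf, hull[:, 0], hull[:, 1], 0, 0, True, 1.0)
            assert np.abs(buf - ref_cov).max() < 1e-5

    def test_raster_converges_to_area_with_resolution(self, geometry, cameras):
        pose = PoseVector17(pitch=45, phi_l=30, phi_r=30)
        sil = silhouette(pose, geometry, cameras[0])
        area = sil.area
        ratios = []
        for scale in (1, 3):
            cam = CameraModel(M=np.diag([scale, scale, 1.0]) @ cameras[0].M,
                              image_width=cameras[0].image_width * scale,
                              image_height=cameras[0].image_height * scale)
            sil2 = silhouette(pose, geometry, cam)
            ratios.append(rasterize(sil2, cam).sum() / scale ** 2 / area)
        assert abs(ratios[1] - 1) < abs(ratios[0] - 1) + 0.01
        assert abs(ratios[1] - 1) < 0.02


class TestClipToRect:
    def test_matches_shapely_box_intersection(self, rng):
        for _ in range(20):
            hull = convex_hull_2d(rng.uniform(-10, 10, size=(10, 2)))
            clipped = clip_polygon_to_rect(hull, -3, 5, -4, 2)
            ref = Polygon(hull).intersection(box(-3, -4, 5, 2))
            assert abs(polygon_area(clipped)) == pytest.approx(
                ref.area, abs=1e-9)
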