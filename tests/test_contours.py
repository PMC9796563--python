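"""Polar contour encoding/decoding: centroid, rays, center-ness, rasterization."""

import numpy as np
import pytest

from polarseg import (
    EmptyMaskError,
    PolarContour,
    Polygon,
    compute_centroid,
    decode_contour,
    extract_rays,
    make_analytic_shape,
    mask_iou,
    polar_centerness,
    rasterize_polygon,
    select_center_samples,
)
from conftest import random_convex_mask


def scan_ray_oracle(mask, center, theta, step=0.25):
    """Independent exhaustive scan: walk outward in fixed steps, remember the
    farthest step whose nearest pixel is foreground."""
    h, w = mask.shape
    best = 0.0
    d = 0.0
    diag = float(np.hypot(h, w))
    while d <= diag:
        x = int(round(center[0] + np.cos(theta) * d))
        y = int(round(center[1] + np.sin(theta) * d))
        if 0 <= x < w and 0 <= y < h and mask[y, x]:
            best = d
        d += step
    return best


class TestCentroid:
    def test_disc_centroid_is_center(self):
        mask, _ = make_analytic_shape("disc", {"center": (50, 50), "radius": 20}, (100, 100))
        cx, cy = compute_centroid(mask)
        assert abs(cx - 50) <= 0.5 and abs(cy - 50) <= 0.5

    def test_single_pixel(self):
        mask = np.zeros((10, 10), bool)
        mask[7, 3] = True  # row 7 = y, col 3 = x
        assert compute_centroid(mask) == (3.0, 7.0)

    def test_l_shape_matches_brute_force_mean(self):
        mask = np.zeros((40, 40), bool)
        mask[5:15, 5:30] = True  # rectangle A
        mask[15:35, 5:12] = True  # rectangle B
        cx, cy = compute_centroid(mask)
        rows, cols = np.nonzero(mask)
        assert cx == pytest.approx(cols.mean()) and cy == pytest.approx(rows.mean())

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            compute_centroid(np.zeros((5, 5), bool))


class TestCenterSamples:
    def test_radius_zero_gives_single_cell(self):
        mask, _ = make_analytic_shape("disc", {"center": (20, 25), "radius": 8}, (50, 50))
        pts = select_center_samples(mask, 0.0)
        assert pts.shape == (1, 2)
        assert tuple(pts[0]) == (20, 25)

    def test_huge_radius_gives_all_foreground(self):
        mask, _ = make_analytic_shape("disc", {"center": (20, 20), "radius": 7}, (40, 40))
        pts = select_center_samples(mask, 1000.0)
        assert len(pts) == mask.sum()

    def test_matches_exhaustive_distance_check(self):
        mask, _ = make_analytic_shape("disc", {"center": (30, 30), "radius": 20}, (60, 60))
        cx, cy = compute_centroid(mask)
        pts = select_center_samples(mask, 3.0)
        expected = {
            (x, y)
            for y, x in zip(*np.nonzero(mask))
            if (x - cx) ** 2 + (y - cy) ** 2 <= 9.0
        }
        expected.add((int(round(cx)), int(round(cy))))
        assert set(map(tuple, pts)) == expected

    def test_negative_radius_rejected(self):
        mask = np.ones((5, 5), bool)
        with pytest.raises(ValueError):
            select_center_samples(mask, -1.0)


class TestExtractRays:
    def test_disc_rays_equal_radius(self):
        mask, _ = make_analytic_shape("disc", {"center": (60, 60), "radius": 20}, (120, 120))
        contour = extract_rays(mask, compute_centroid(mask), 36)
        assert np.all(np.abs(contour.ray_lengths - 20) <= 0.71)

    def test_square_axis_and_diagonal(self):
        mask, _ = make_analytic_shape("square", {"center": (60, 60), "half_width": 25}, (120, 120))
        contour = extract_rays(mask, compute_centroid(mask), 8)  # every 45 degrees
        axis = contour.ray_lengths[[0, 2, 4, 6]]
        diag = contour.ray_lengths[[1, 3, 5, 7]]
        assert np.all(np.abs(axis - 25) <= 1.0)
        assert np.all(np.abs(diag - 25 * np.sqrt(2)) <= 1.0)

    def test_center_outside_object_rays_away_are_zero(self):
        mask, _ = make_analytic_shape("disc", {"center": (80, 40), "radius": 15}, (80, 120))
        contour = extract_rays(mask, (10.0, 40.0), 36)
        # ray pointing at the disc (along +x) is long; ray pointing away is 0
        assert contour.ray_lengths[0] > 60
        assert contour.ray_lengths[18] == 0.0

    def test_center_out_of_bounds_raises(self):
        mask = np.ones((20, 20), bool)
        with pytest.raises(ValueError):
            extract_rays(mask, (25.0, 5.0), 36)

    def test_empty_mask_warns_all_zero(self):
        with pytest.warns(UserWarning):
            contour = extract_rays(np.zeros((20, 20), bool), (10.0, 10.0), 36)
        assert np.all(contour.ray_lengths == 0)

    def test_concave_mask_takes_farthest_foreground(self):
        # two horizontal bars with a gap; a ray along +x crosses the gap
        mask = np.zeros((21, 60), bool)
        mask[9:12, 0:20] = True
        mask[9:12, 40:55] = True
        contour = extract_rays(mask, (5.0, 10.0), 4)
        assert contour.ray_lengths[0] >= 49.0  # reaches the far bar

    def test_agrees_with_scan_oracle_on_seeded_convex_shapes(self, rng):
        for _ in range(20):
            mask = random_convex_mask(rng)
            center = compute_centroid(mask)
            contour = extract_rays(mask, center, 12)
            for a, theta in enumerate(contour.angles):
                oracle = scan_ray_oracle(mask, center, theta)
                assert abs(contour.ray_lengths[a] - oracle) <= 0.25 + 1e-9


class TestCenterness:
    @pytest.mark.parametrize(
        "rays,expected",
        [
            (np.full(36, 7.0), 1.0),
            (np.tile([5.0, 10.0], 18), 0.5),
            (np.array([0.0, 3.0, 4.0]), 0.0),
            (np.zeros(36), 0.0),
        ],
    )
    def test_min_over_max(self, rays, expected):
        assert polar_centerness(rays) == pytest.approx(expected)

    def test_offset_disc_law(self):
        """For a disc of radius R encoded about a center offset by d, the
        min/max ray ratio is (R-d)/(R+d), strictly decreasing in d."""
        R = 40
        mask, _ = make_analytic_shape("disc", {"center": (100, 100), "radius": R}, (200, 200))
        values = []
        for d in (0.0, R / 4, R / 2, 3 * R / 4):
            cn = polar_centerness(extract_rays(mask, (100 + d, 100.0), 36))
            assert abs(cn - (R - d) / (R + d)) <= 0.05
            values.append(cn)
        assert all(a > b for a, b in zip(values, values[1:]))


class TestDecodeRasterize:
    def test_single_ray_axis_vertices(self):
        contour = PolarContour((0.0, 0.0), np.array([10.0, 5.0, 10.0, 5.0]))
        verts = decode_contour(contour).vertices
        assert verts[0] == pytest.approx([10.0, 0.0])
        assert verts[1] == pytest.approx([0.0, 5.0])  # 90 degrees: +y (down-screen)

    def test_equal_rays_give_regular_polygon(self):
        contour = PolarContour((50.0, 50.0), np.full(36, 20.0))
        verts = decode_contour(contour).vertices
        radii = np.hypot(verts[:, 0] - 50, verts[:, 1] - 50)
        assert np.allclose(radii, 20.0)
        # interior angle spacing exact to floating precision
        ang = np.arctan2(verts[:, 1] - 50, verts[:, 0] - 50)
        diffs = np.diff(np.unwrap(ang))
        assert np.allclose(diffs, 2 * np.pi / 36)

    def test_decode_analytic_polar_description_exact(self):
        _, contour = make_analytic_shape(
            "ellipse", {"center": (80.0, 70.0), "semi_axes": (30.0, 18.0)}, (160, 160)
        )
        verts = decode_contour(contour).vertices
        theta = contour.angles
        assert np.allclose(verts[:, 0], np.cos(theta) * contour.ray_lengths + 80.0)
        assert np.allclose(verts[:, 1], np.sin(theta) * contour.ray_lengths + 70.0)

    def test_regular_36gon_area(self):
        R = 30.0
        contour = PolarContour((60.0, 60.0), np.full(36, R))
        mask = rasterize_polygon(decode_contour(contour), 120, 120)
        exact = 0.5 * 36 * R**2 * np.sin(2 * np.pi / 36)
        assert abs(mask.sum() - exact) / exact < 0.015

    def test_triangle_matches_point_in_polygon_oracle(self):
        verts = np.array([(3.0, 2.0), (17.0, 5.0), (6.0, 14.0)])
        mask = rasterize_polygon(Polygon(verts), 20, 20)
        # brute-force even-odd crossing test at pixel centers
        def inside(px, py):
            crossings = 0
            for (x1, y1), (x2, y2) in zip(verts, np.roll(verts, -1, axis=0)):
                if (y1 > py) != (y2 > py):
                    xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < xint:
                        crossings += 1
            return crossings % 2 == 1
        brute = np.array([[inside(x, y) for x in range(20)] for y in range(20)])
        assert (mask ^ brute).sum() <= 6  # boundary pixels may differ

    def test_polygon_outside_image_empty(self):
        verts = np.array([(200.0, 200.0), (220.0, 200.0), (210.0, 220.0)])
        assert rasterize_polygon(Polygon(verts), 50, 50).sum() == 0

    def test_degenerate_polygon_warns_empty(self):
        verts = np.array([(1.0, 1.0), (5.0, 5.0), (9.0, 9.0)])
        with pytest.warns(UserWarning):
            mask = rasterize_polygon(Polygon(verts), 20, 20)
        assert mask.sum() == 0


class TestMaskIoU:
    def test_identical_and_disjoint(self):
        a = np.zeros((10, 10), bool)
        a[2:5, 2:5] = True
        b = np.zeros((10, 10), bool)
        b[6:9, 6:9] = True
        assert mask_iou(a, a) == 1.0
        assert mask_iou(a, b) == 0.0
        assert mask_iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 0.0

    def test_nested_discs_area_ratio(self):
        small, _ = make_analytic_shape("disc", {"center": (50, 50), "radius": 5}, (100, 100))
        big, _ = make_analytic_shape("disc", {"center": (50, 50), "radius": 10}, (100, 100))
        assert abs(mask_iou(small, big) - 0.25) <= 0.02

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mask_iou(np.ones((3, 3), bool), np.ones((4, 4), bool))


class TestRoundTrip:
    @pytest.mark.parametrize(
        "kind,params",
        [
            ("disc", {"center": (80, 80), "radius": 30}),
            ("ellipse", {"center": (80, 80), "semi_axes": (45, 25)}),
            ("square", {"center": (80, 80), "half_width": 28}),
            ("n_gon", {"center": (80, 80), "circumradius": 35, "n_sides": 6}),
        ],
    )
    def test_encode_decode_rasterize_iou(self, kind, params):
        mask, _ = make_analytic_shape(kind, params, (160, 160))
        contour = extract_rays(mask, compute_centroid(mask), 36)
        rec = rasterize_polygon(decode_contour(contour), 160, 160)
        assert mask_iou(mask, rec) >= 0.95
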