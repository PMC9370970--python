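"""The four irregularity features: ratios, Hausdorff distance, IoU."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import directed_hausdorff as scipy_dh

import tubershape as ts
from tubershape.contour import Contour
from tubershape.errors import EmptyMaskError, ExtentMismatchError
from tubershape.synthetic import polar_area

from test_contour import ellipse_polygon


def brute_force_directed(P, Q):
    """Literal O(n*m) double loop over both point sets."""
    worst = 0.0
    for p in P:
        best = math.inf
        for q in Q:
            d = ((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2) ** 0.5
            if d < best:
                best = d
        if best > worst:
            worst = best
    return worst


class TestRatios:
    def test_self_ratio_is_one(self):
        e = ts.EllipseParams(100, 100, 80, 50, 0.4)
        c = ellipse_polygon(80, 50, n=2000, cx=100, cy=100, theta=0.4)
        assert ts.perimeter_ratio(c, e) == pytest.approx(1.0, rel=5e-3)
        assert ts.area_ratio(c, e) == pytest.approx(1.0, rel=5e-3)

    def test_scaling_contour_scales_ratios(self):
        e = ts.EllipseParams(0, 0, 80, 50, 0.0)
        c1 = ellipse_polygon(80, 50, n=1000)
        c2 = Contour(c1.points * 2)
        assert ts.perimeter_ratio(c2, e) == pytest.approx(2 * ts.perimeter_ratio(c1, e), rel=1e-9)
        assert ts.area_ratio(c2, e) == pytest.approx(4 * ts.area_ratio(c1, e), rel=1e-9)

    def test_star_perturbed_ellipse_inflates_perimeter_ratio(self):
        # 6 lobes at 0.3 of the local radius vs its own least-squares ellipse
        spec = ts.ShapeSpec(a=100, b=60, lobe_count=6, lobe_amplitude=0.3,
                            center=(0.0, 0.0))
        phi = np.linspace(0, 2 * np.pi, 3000, endpoint=False)
        r = ts.radial_profile(spec, phi)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        e = ts.fit_ellipse_lsq(pts)
        assert ts.perimeter_ratio(Contour(pts), e) > 1.05

    def test_lobed_area_matches_polar_integral(self):
        spec = ts.ShapeSpec(a=100, b=60, lobe_count=5, lobe_amplitude=0.15,
                            center=(0.0, 0.0))
        phi = np.linspace(0, 2 * np.pi, 5000, endpoint=False)
        r = ts.radial_profile(spec, phi)
        poly = Contour(np.column_stack([r * np.cos(phi), r * np.sin(phi)]))
        assert ts.polygon_area(poly) == pytest.approx(polar_area(spec), rel=0.01)


class TestHausdorff:
    def test_directed_examples(self):
        P = np.array([[0.0, 0.0], [10.0, 0.0]])
        Q = np.array([[0.0, 0.0]])
        assert ts.directed_hausdorff(P, Q) == 10.0
        assert ts.directed_hausdorff(Q, P) == 0.0

    def test_bidirectional_examples(self):
        P = np.array([[0.0, 0.0], [10.0, 0.0]])
        Q = np.array([[0.0, 0.0]])
        assert ts.hausdorff(P, Q) == 10.0
        assert ts.hausdorff(Q, P) == 10.0  # symmetric
        assert ts.hausdorff(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])) == 5.0

    def test_identity(self, rng):
        P = rng.uniform(0, 100, size=(50, 2))
        assert ts.hausdorff(P, P) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ts.hausdorff(np.empty((0, 2)), np.array([[0.0, 0.0]]))

    def test_equals_brute_force_loop_exactly(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            P = rng.uniform(0, 500, size=(rng.integers(5, 200), 2))
            Q = rng.uniform(0, 500, size=(rng.integers(5, 200), 2))
            assert ts.directed_hausdorff(P, Q) == brute_force_directed(P, Q)
            assert ts.hausdorff(P, Q) == max(brute_force_directed(P, Q),
                                             brute_force_directed(Q, P))

    def test_agrees_with_scipy_reference(self, rng):
        P = rng.uniform(0, 100, size=(80, 2))
        Q = rng.uniform(0, 100, size=(120, 2))
        assert ts.directed_hausdorff(P, Q) == pytest.approx(scipy_dh(P, Q)[0], abs=1e-12)

    def test_triangle_inequality(self, rng):
        for _ in range(30):
            A = rng.uniform(0, 50, size=(20, 2))
            B = rng.uniform(0, 50, size=(25, 2))
            C = rng.uniform(0, 50, size=(15, 2))
            assert ts.hausdorff(A, C) <= ts.hausdorff(A, B) + ts.hausdorff(B, C) + 1e-9


class TestIoU:
    def test_identical_masks(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        assert ts.mask_iou(m, m) == 1.0

    def test_disjoint_masks(self):
        m1 = np.zeros((20, 20), dtype=bool); m1[:5, :5] = True
        m2 = np.zeros((20, 20), dtype=bool); m2[10:, 10:] = True
        assert ts.mask_iou(m1, m2) == 0.0

    def test_half_offset_squares(self):
        # two 10x10 squares offset by 5 in x: overlap 50, union 150
        m1 = np.zeros((30, 30), dtype=bool); m1[10:20, 5:15] = True
        m2 = np.zeros((30, 30), dtype=bool); m2[10:20, 10:20] = True
        assert ts.mask_iou(m1, m2) == pytest.approx(1 / 3)

    def test_extent_mismatch_rejected(self):
        with pytest.raises(ExtentMismatchError):
            ts.mask_iou(np.ones((5, 5), dtype=bool), np.ones((6, 5), dtype=bool))

    def test_both_empty_rejected(self):
        with pytest.raises(EmptyMaskError):
            ts.mask_iou(np.zeros((5, 5), dtype=bool), np.zeros((5, 5), dtype=bool))

    def test_invariant_under_common_translation(self):
        m1 = np.zeros((40, 40), dtype=bool); m1[5:20, 5:20] = True
        m2 = np.zeros((40, 40), dtype=bool); m2[10:25, 8:23] = True
        base = ts.mask_iou(m1, m2)
        s1 = np.roll(m1, (7, 9), axis=(0, 1))
        s2 = np.roll(m2, (7, 9), axis=(0, 1))
        assert ts.mask_iou(s1, s2) == base

    def test_monotone_as_square_slides_away(self):
        m1 = np.zeros((40, 80), dtype=bool); m1[10:30, 10:30] = True
        prev = 1.0
        for dx in range(0, 25, 4):
            m2 = np.roll(m1, dx, axis=1)
            cur = ts.mask_iou(m1, m2)
            assert cur <= prev
            prev = cur

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 11), st.integers(0, 11), st.integers(1, 8), st.integers(1, 8))
    def test_bounded_in_unit_interval(self, x, y, w, h):
        m1 = np.zeros((20, 20), dtype=bool); m1[5:15, 5:15] = True
        m2 = np.zeros((20, 20), dtype=bool); m2[y:y + h, x:x + w] = True
        v = ts.mask_iou(m1, m2)
        assert 0.0 <= v <= 1.0
        assert (v == 1.0) == np.array_equal(m1, m2)


class TestComputeFeatures:
    def test_exact_ellipse_blob(self, regular_mask):
        feats, _, _ = ts.compute_features(regular_mask)
        assert feats.hausdorff <= 2.0
        assert feats.iou >= 0.98
        assert 0.98 <= feats.perimeter_ratio <= 1.02
        assert 0.98 <= feats.area_ratio <= 1.02

    def test_lobed_blob_crosses_both_thresholds(self, irregular_mask):
        feats, _, _ = ts.compute_features(irregular_mask)
        assert feats.hausdorff > 21.0
        assert feats.iou < 0.925

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            ts.compute_features(np.zeros((410, 614), dtype=bool))

    def test_hausdorff_scale_covariance(self):
        # doubling the canvas and the shape doubles H within raster error,
        # which is what couples the pixel threshold to the working resolution
        for seed in (11, 12, 13, 14, 15):
            rng = np.random.default_rng(seed)
            spec = ts.ShapeSpec(a=rng.uniform(60, 90), b=rng.uniform(40, 55),
                                theta=rng.uniform(0, np.pi),
                                center=(307.0, 205.0), lobe_count=int(rng.integers(3, 7)),
                                lobe_amplitude=rng.uniform(0.2, 0.3),
                                lobe_phase=rng.uniform(0, 2 * np.pi), seed=seed)
            from tubershape.synthetic import truth_mask
            m1 = truth_mask(spec, (410, 614))
            big = ts.ShapeSpec(a=spec.a * 2, b=spec.b * 2, theta=spec.theta,
                               center=(614.0, 410.0), lobe_count=spec.lobe_count,
                               lobe_amplitude=spec.lobe_amplitude,
                               lobe_phase=spec.lobe_phase, seed=seed)
            m2 = truth_mask(big, (820, 1228))
            h1 = ts.compute_features(m1)[0].hausdorff
            h2 = ts.compute_features(m2)[0].hausdorff
            assert abs(h2 - 2 * h1) <= 2.0
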