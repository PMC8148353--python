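"""Kappa, dice, and radial boundary-distance metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from trace_concord import (
    BoundingBox,
    InputError,
    MetricError,
    TraceMask,
    average_boundary_distance,
    border_kappa,
    centroid,
    dice,
    interpret_kappa,
    radial_distance,
    region_kappa,
    union_bounding_box,
)
from trace_concord.agreement_metrics import ANGLES_UNIFORM30, border_band

from oracles import circle_mask, kappa_contingency, mu_d_polar, polar_shape_mask


def _block(shape, rows, cols):
    g = np.zeros(shape, dtype=bool)
    g[rows[0] : rows[1] + 1, cols[0] : cols[1] + 1] = True
    return TraceMask(g)


class TestBoundingBox:
    def test_single_block(self):
        bbox = union_bounding_box([_block((20, 20), (4, 6), (9, 11))], margin=0)
        assert (bbox.x_min, bbox.y_min, bbox.x_max, bbox.y_max) == (9, 4, 11, 6)

    def test_two_disjoint_blocks(self):
        a = _block((30, 30), (2, 4), (3, 5))
        b = _block((30, 30), (20, 25), (22, 27))
        bbox = union_bounding_box([a, b])
        assert (bbox.x_min, bbox.y_min, bbox.x_max, bbox.y_max) == (3, 2, 27, 25)

    def test_margin_clipped_to_image(self):
        bbox = union_bounding_box([_block((10, 10), (4, 6), (4, 6))], margin=100)
        assert (bbox.x_min, bbox.y_min, bbox.x_max, bbox.y_max) == (0, 0, 9, 9)

    def test_all_empty_rejected(self):
        with pytest.raises(InputError):
            union_bounding_box([TraceMask(np.zeros((5, 5), dtype=bool))])


class TestRegionKappa:
    def test_identical_masks(self):
        m = _block((32, 32), (8, 20), (10, 22))
        bbox = union_bounding_box([m], margin=3)
        res = region_kappa(m, m, bbox)
        assert res.kappa == 1.0 and res.p_observed == 1.0

    def test_exact_complements_at_half(self):
        a = _block((32, 32), (0, 31), (0, 15))
        b = _block((32, 32), (0, 31), (16, 31))
        bbox = BoundingBox(0, 0, 31, 31)
        res = region_kappa(a, b, bbox)
        assert res.p_observed == 0.0
        assert res.p_expected == pytest.approx(0.5)
        assert res.kappa == pytest.approx(-1.0)

    def test_degenerate_equal_constant_box(self):
        a = _block((16, 16), (2, 5), (2, 5))
        bbox = BoundingBox(10, 10, 14, 14)  # blank corner for both masks
        assert region_kappa(a, a, bbox).kappa == 1.0

    @given(
        data=hnp.arrays(np.bool_, (2, 32, 32), elements=st.booleans()),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_contingency_oracle(self, data):
        a, b = TraceMask(data[0]), TraceMask(data[1])
        bbox = BoundingBox(0, 0, 31, 31)
        res = region_kappa(a, b, bbox)
        k, po, pe = kappa_contingency(data[0], data[1])
        assert res.kappa == pytest.approx(k, abs=1e-12)
        assert res.p_observed == pytest.approx(po, abs=1e-12)
        assert res.p_expected == pytest.approx(pe, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(InputError):
            region_kappa(
                _block((10, 10), (1, 3), (1, 3)),
                _block((12, 12), (1, 3), (1, 3)),
                BoundingBox(0, 0, 9, 9),
            )


class TestBorderKappa:
    def test_identical_masks_give_one(self, circle_trace):
        m = circle_trace(radius=50)
        bbox = union_bounding_box([m], margin=5)
        for tol in (0, 1, 2, 4):
            assert border_kappa(m, m, bbox, tolerance=tol).kappa == 1.0

    def test_disjoint_bands_near_chance(self, circle_trace):
        big, small = circle_trace(radius=50), circle_trace(radius=40)
        bbox = union_bounding_box([big, small])
        res = border_kappa(big, small, bbox, tolerance=2)
        k_oracle, _, _ = kappa_contingency(
            border_band(big, 2).pixels[bbox.y_min : bbox.y_max + 1, bbox.x_min : bbox.x_max + 1],
            border_band(small, 2).pixels[bbox.y_min : bbox.y_max + 1, bbox.x_min : bbox.x_max + 1],
        )
        assert res.kappa == pytest.approx(k_oracle, abs=1e-12)
        assert res.kappa < 0.1  # bands are disjoint: no real agreement

    def test_overlap_monotonicity(self, circle_trace):
        big = circle_trace(radius=50)
        near, far = circle_trace(radius=49), circle_trace(radius=40)
        k_near = border_kappa(big, near, union_bounding_box([big, near]), tolerance=2).kappa
        k_far = border_kappa(big, far, union_bounding_box([big, far]), tolerance=2).kappa
        assert k_near > k_far


class TestDice:
    def test_identical(self, circle_trace):
        m = circle_trace(radius=30)
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = _block((20, 20), (0, 4), (0, 4))
        b = _block((20, 20), (10, 14), (10, 14))
        assert dice(a, b) == 0.0

    def test_half_overlap_arithmetic(self):
        a = _block((30, 30), (0, 9), (0, 9))  # 100 px
        b = _block((30, 30), (5, 14), (0, 9))  # 100 px, 50 shared
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_rejected(self):
        e = TraceMask(np.zeros((5, 5), dtype=bool))
        with pytest.raises(InputError):
            dice(e, e)


class TestCentroid:
    def test_rectangle(self):
        m = _block((10, 12), (0, 4), (0, 9))
        assert centroid(m) == (4.5, 2.0)

    def test_single_pixel(self):
        g = np.zeros((10, 10), dtype=bool)
        g[3, 7] = True
        assert centroid(TraceMask(g)) == (7.0, 3.0)

    def test_rasterized_circle_subpixel(self, circle_trace):
        cx, cy = centroid(circle_trace(center=(50.0, 50.0), radius=30, shape=(101, 101)))
        assert abs(cx - 50) < 0.1 and abs(cy - 50) < 0.1


class TestRadialDistance:
    def test_circle_radius_any_angle(self, circle_trace):
        m = circle_trace(radius=40)
        for ang in (0, 33, 90, 151, 270):
            assert radial_distance(m, (100, 100), ang) == pytest.approx(40, abs=0.5)

    def test_square_corner_geometry(self):
        # along the diagonal the pixel-rounding quantization is half a
        # pixel diagonal (~0.71 px), slightly larger than on-axis
        m = _block((41, 41), (10, 30), (10, 30))  # half-width 10 around (20, 20)
        assert radial_distance(m, (20, 20), 45) == pytest.approx(10 * np.sqrt(2), abs=0.75)

    def test_farthest_pixel_rule_with_detached_arc(self):
        # disc edge at 45 px; a stray misaligned arc crosses the 90-degree
        # ray near 60 px -> the farthest-foreground rule must report the arc
        h = w = 201
        yy, xx = np.mgrid[0:h, 0:w]
        rho = np.hypot(xx - 100, yy - 100)
        theta = np.degrees(np.arctan2(yy - 100, xx - 100)) % 360
        disc = rho <= 45
        arc = (np.abs(rho - 60) <= 0.8) & (theta >= 80) & (theta <= 100)
        d = radial_distance(TraceMask(disc | arc), (100, 100), 90)
        assert d == pytest.approx(60, abs=1.0)

    def test_no_hit_is_nan(self):
        g = np.zeros((50, 50), dtype=bool)
        g[5:10, 5:10] = True
        assert np.isnan(radial_distance(TraceMask(g), (40.0, 40.0), 0.0))


class TestAverageBoundaryDistance:
    def test_identical_masks_zero(self, circle_trace):
        m = circle_trace(radius=50)
        prof = average_boundary_distance(m, m)
        assert prof.mu_d == 0.0
        assert prof.n_valid == 12

    def test_concentric_circles(self, circle_trace):
        prof = average_boundary_distance(circle_trace(radius=50), circle_trace(radius=40))
        assert prof.mu_d == pytest.approx(10, abs=0.5)
        assert np.all(np.abs(np.abs(prof.d_ref - prof.d_test) - 10) <= 0.5)

    def test_single_arc_against_dense_oracle(self):
        # reference circle r=50; test pushes one 30-degree arc to r=58
        def r_ref(a):
            return np.full_like(np.asarray(a, dtype=float), 50.0)

        def r_test(a):
            a = np.asarray(a, dtype=float) % 360
            return np.where((a >= 75) & (a < 105), 58.0, 50.0)

        ref = TraceMask(polar_shape_mask((201, 201), (100, 100), r_ref))
        test = TraceMask(polar_shape_mask((201, 201), (100, 100), r_test))
        prof = average_boundary_distance(ref, test)
        dense = mu_d_polar(r_ref, r_test, np.arange(0, 360, 0.1))
        assert prof.mu_d == pytest.approx(dense, abs=0.5)
        # with the default 30-degree grid exactly one direction is affected
        affected = np.abs(prof.d_ref - prof.d_test) > 4
        assert affected.sum() == 1

    def test_asymmetric_in_arguments(self, circle_trace):
        ref = circle_trace(center=(100.0, 100.0), radius=40)
        test = circle_trace(center=(115.0, 100.0), radius=20)
        ab = average_boundary_distance(ref, test).mu_d
        ba = average_boundary_distance(test, ref).mu_d
        # radii are cast from each reference's own centroid
        assert ab != pytest.approx(ba, abs=1e-6)

    def test_all_angles_undefined(self):
        ref = np.zeros((60, 60), dtype=bool)
        ref[28:32, 28:32] = True
        # single test pixel lying on neither the 0- nor the 90-degree ray
        test = np.zeros((60, 60), dtype=bool)
        test[58, 2] = True
        with pytest.raises(MetricError):
            average_boundary_distance(TraceMask(ref), TraceMask(test), angles=[0.0, 90.0])


class TestJointTranslationInvariance:
    def test_metrics_shift_invariant(self, circle_trace):
        a0 = circle_trace(shape=(220, 220), center=(90.0, 90.0), radius=40)
        b0 = circle_trace(shape=(220, 220), center=(95.0, 90.0), radius=36)
        a1 = circle_trace(shape=(220, 220), center=(120.0, 115.0), radius=40)
        b1 = circle_trace(shape=(220, 220), center=(125.0, 115.0), radius=36)
        bb0 = union_bounding_box([a0, b0])
        bb1 = union_bounding_box([a1, b1])
        assert dice(a0, b0) == dice(a1, b1)
        assert region_kappa(a0, b0, bb0).kappa == pytest.approx(
            region_kappa(a1, b1, bb1).kappa, abs=1e-12
        )
        assert border_kappa(a0, b0, bb0).kappa == pytest.approx(
            border_kappa(a1, b1, bb1).kappa, abs=1e-12
        )
        assert average_boundary_distance(a0, b0).mu_d == pytest.approx(
            average_boundary_distance(a1, b1).mu_d, abs=1e-9
        )


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.87, "almost perfect"),
            (0.21, "fair"),
            (-0.1, "less than chance"),
            (1.0, "almost perfect"),
        ],
    )
    def test_anchors(self, value, band):
        assert interpret_kappa(value) == band

    @pytest.mark.parametrize(
        "edge,below,above",
        [
            (0.005, "less than chance", "poor"),
            (0.205, "poor", "fair"),
            (0.405, "fair", "moderate"),
            (0.605, "moderate", "substantial"),
            (0.805, "substantial", "almost perfect"),
        ],
    )
    def test_band_edges(self, edge, below, above):
        assert interpret_kappa(edge - 1e-9) == below
        assert interpret_kappa(edge) == above

    def test_above_one_rejected(self):
        with pytest.raises(InputError):
            interpret_kappa(1.01)

    @given(st.floats(min_value=-5.0, max_value=1.0))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_every_value_has_a_band(self, k):
        assert interpret_kappa(k) in {
            "less than chance",
            "poor",
            "fair",
            "moderate",
            "substantial",
            "almost perfect",
        }
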