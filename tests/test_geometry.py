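"""Box algebra and the Shape-IoU loss family."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pigpen_mot.geometry import (
    Box,
    ShapeIoUParams,
    ciou_loss,
    convert_box,
    diou_loss,
    iou,
    iou_matrix,
    shape_distance,
    shape_iou_loss,
    shape_omega,
    shape_weights,
)

coord = st.floats(-500, 500, allow_nan=False)
side = st.floats(0.5, 200, allow_nan=False)
boxes = st.builds(Box, cx=coord, cy=coord, w=side, h=side)


class TestBoxValidation:
    @pytest.mark.parametrize("w,h", [(0, 1), (-1, 1), (1, 0), (1, -2)])
    def test_nonpositive_sides_rejected(self, w, h):
        with pytest.raises(ValueError):
            Box(0, 0, w, h)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            Box(math.nan, 0, 1, 1)


class TestIoU:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (Box(0, 0, 2, 2), Box(0, 0, 2, 2), 1.0),
            (Box(0, 0, 2, 2), Box(10, 10, 2, 2), 0.0),
            # intersection 1x2 = 2, union 4 + 4 - 2 = 6
            (Box(0, 0, 2, 2), Box(1, 0, 2, 2), 1.0 / 3.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert iou(a, b) == pytest.approx(expected, abs=1e-12)

    @given(a=boxes, b=boxes)
    @settings(max_examples=200, derandomize=True)
    def test_range_and_symmetry(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert iou(b, a) == pytest.approx(v, abs=1e-12)

    def test_matrix_agrees_with_scalar(self, rng):
        a = rng.uniform(0, 100, (5, 4)) + [0, 0, 1, 1]
        b = rng.uniform(0, 100, (7, 4)) + [0, 0, 1, 1]
        m = iou_matrix(a, b)
        for i in range(5):
            for j in range(7):
                expected = iou(Box.from_tlwh(*a[i]), Box.from_tlwh(*b[j]))
                assert m[i, j] == pytest.approx(expected, abs=1e-12)


class TestShapeWeights:
    def test_scale_zero_gives_unit_weights(self):
        assert shape_weights(Box(3, 7, 5, 2), 0.0) == (1.0, 1.0)

    def test_square_gt_gives_unit_weights(self):
        ww, hh = shape_weights(Box(0, 0, 3, 3), 1.7)
        assert ww == pytest.approx(1.0) and hh == pytest.approx(1.0)

    def test_wide_gt(self):
        # direct evaluation: 2*4/(4+2), 2*2/(4+2)
        ww, hh = shape_weights(Box(0, 0, 4, 2), 1.0)
        assert ww == pytest.approx(4.0 / 3.0)
        assert hh == pytest.approx(2.0 / 3.0)

    @given(gt=boxes, scale=st.floats(0, 3, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_weights_sum_to_two(self, gt, scale):
        ww, hh = shape_weights(gt, scale)
        assert ww + hh == pytest.approx(2.0, abs=1e-12)
        assert 0.0 < ww < 2.0 and 0.0 < hh < 2.0


class TestShapeDistance:
    def test_concentric_is_zero(self):
        assert shape_distance(Box(5, 5, 2, 8), Box(5, 5, 6, 2), 0.7) == 0.0

    def test_unit_offset(self):
        # enclosing box 3x2 -> c^2 = 13; scale=0 -> hh = 1
        assert shape_distance(Box(1, 0, 2, 2), Box(0, 0, 2, 2), 0.0) == pytest.approx(1 / 13)
        assert shape_distance(Box(0, 1, 2, 2), Box(0, 0, 2, 2), 0.0) == pytest.approx(1 / 13)

    @given(pred=boxes, gt=boxes, dx=coord, dy=coord)
    @settings(max_examples=200, derandomize=True)
    def test_translation_invariance(self, pred, gt, dx, dy):
        d0 = shape_distance(pred, gt, 0.5)
        shifted = shape_distance(
            Box(pred.cx + dx, pred.cy + dy, pred.w, pred.h),
            Box(gt.cx + dx, gt.cy + dy, gt.w, gt.h),
            0.5,
        )
        assert shifted == pytest.approx(d0, rel=1e-9, abs=1e-12)

    def test_scale_zero_matches_plain_arithmetic_oracle(self, rng):
        # with unit weights the term reduces to the unweighted normalized
        # squared center offset, computable by independent direct arithmetic
        for _ in range(200):
            p = Box(*(rng.uniform(-50, 50, 2)), *(rng.uniform(1, 40, 2)))
            g = Box(*(rng.uniform(-50, 50, 2)), *(rng.uniform(1, 40, 2)))
            cw = max(p.cx + p.w / 2, g.cx + g.w / 2) - min(p.cx - p.w / 2, g.cx - g.w / 2)
            ch = max(p.cy + p.h / 2, g.cy + g.h / 2) - min(p.cy - p.h / 2, g.cy - g.h / 2)
            expected = ((p.cx - g.cx) ** 2 + (p.cy - g.cy) ** 2) / (cw**2 + ch**2)
            assert shape_distance(p, g, 0.0) == pytest.approx(expected, rel=1e-12)


class TestShapeOmega:
    def test_same_shape_is_zero(self):
        assert shape_omega(Box(9, -4, 3, 5), Box(0, 0, 3, 5), 1.2, 4.0) == 0.0

    def test_width_mismatch(self):
        # omega_w = 1 * 2/4 = 0.5, omega_h = 0
        expected = (1 - math.exp(-0.5)) ** 4
        assert shape_omega(Box(0, 0, 2, 2), Box(0, 0, 4, 2), 0.0, 4.0) == pytest.approx(expected)

    def test_theta_one_closed_form(self):
        expected = 1 - math.exp(-0.5)
        assert shape_omega(Box(0, 0, 2, 2), Box(0, 0, 4, 2), 0.0, 1.0) == pytest.approx(expected)

    @given(pred=boxes, gt=boxes, k=st.floats(0.1, 10, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_joint_uniform_scaling_invariance(self, pred, gt, k):
        v0 = shape_omega(pred, gt, 0.0, 4.0)
        vs = shape_omega(
            Box(pred.cx * k, pred.cy * k, pred.w * k, pred.h * k),
            Box(gt.cx * k, gt.cy * k, gt.w * k, gt.h * k),
            0.0,
            4.0,
        )
        assert vs == pytest.approx(v0, rel=1e-9, abs=1e-12)


class TestShapeIoULoss:
    def test_identical_boxes_zero_loss(self):
        b = shape_iou_loss(Box(3, 4, 5, 6), Box(3, 4, 5, 6))
        assert b.loss == 0.0 and b.iou == 1.0

    def test_offset_case(self):
        b = shape_iou_loss(Box(1, 0, 2, 2), Box(0, 0, 2, 2), ShapeIoUParams(scale=0.0))
        assert b.loss == pytest.approx(1 - 1 / 3 + 1 / 13, abs=1e-9)
        assert b.omega_shape == 0.0

    def test_concentric_scale_case(self):
        b = shape_iou_loss(Box(0, 0, 2, 2), Box(0, 0, 4, 4), ShapeIoUParams(scale=0.0, theta=4.0))
        # IoU = 4/16; omega has two equal (1 - e^{-0.5})^4 terms
        expected = 0.75 + (2 * (1 - math.exp(-0.5)) ** 4) / 2
        assert b.loss == pytest.approx(expected, abs=1e-9)

    @given(pred=boxes, gt=boxes, scale=st.floats(0, 2, allow_nan=False))
    @settings(max_examples=300, derandomize=True)
    def test_nonnegative_and_breakdown_identity(self, pred, gt, scale):
        b = shape_iou_loss(pred, gt, ShapeIoUParams(scale=scale))
        assert b.loss >= 0.0
        assert b.loss == pytest.approx(1 - b.iou + b.distance_shape + b.omega_shape / 2, abs=1e-12)

    def test_monotone_in_horizontal_offset(self):
        gt = Box(0, 0, 10, 6)
        losses = [shape_iou_loss(Box(dx, 0, 10, 6), gt).loss for dx in np.linspace(0, 30, 40)]
        assert all(b >= a - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_comparison_baselines_vanish_at_identity(self):
        assert diou_loss(Box(1, 2, 3, 4), Box(1, 2, 3, 4)) == pytest.approx(0.0)
        assert ciou_loss(Box(1, 2, 3, 4), Box(1, 2, 3, 4)) == pytest.approx(0.0)


class TestConvertBox:
    def test_center_to_corners(self):
        assert convert_box((0, 0, 2, 2), "center", "corners") == (-1, -1, 1, 1)

    def test_tlwh_to_center(self):
        assert convert_box((10, 20, 4, 6), "tlwh", "center") == Box(12, 23, 4, 6)

    def test_yolo_to_center(self):
        b = convert_box((0.5, 0.5, 0.1, 0.2), "yolo", "center", image_size=(100, 100))
        assert b == Box(50, 50, 10, 20)

    @pytest.mark.parametrize("conv", ["tlwh", "corners", "yolo"])
    def test_round_trip(self, conv, rng):
        for _ in range(50):
            vals = (float(rng.uniform(10, 90)), float(rng.uniform(10, 90)),
                    float(rng.uniform(1, 20)), float(rng.uniform(1, 20)))
            out = convert_box(
                convert_box(vals, "center", conv, image_size=(128, 96)),
                conv, "center", image_size=(128, 96),
            )
            for got, want in zip((out.cx, out.cy, out.w, out.h), vals):
                assert got == pytest.approx(want, abs=1e-9)

    def test_unknown_convention(self):
        with pytest.raises(ValueError, match="unknown box convention"):
            convert_box((0, 0, 1, 1), "center", "polar")

    def test_yolo_requires_image_size(self):
        with pytest.raises(ValueError, match="image_size"):
            convert_box((0.5, 0.5, 0.1, 0.1), "yolo", "center")
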