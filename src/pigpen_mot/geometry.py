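"""Axis-aligned bounding-box algebra and the Shape-IoU regression loss.

Boxes live in continuous pixel coordinates with the origin at the top-left
corner and y increasing downward, parameterized by their center ``(cx, cy)``
and side lengths ``(w, h)``.  The Shape-IoU loss augments ``1 - IoU`` with a
shape-weighted normalized center-distance term and a shape-discrepancy term

    L = 1 - IoU + distance_shape + Omega_shape / 2

where the weights ``ww`` and ``hh`` derive from the ground-truth box aspect
through a dataset-dependent ``scale`` exponent, the center distance is
normalized by the diagonal of the minimal box enclosing both operands, and
Omega_shape penalizes width/height mismatch through ``(1 - e^{-omega})^theta``
with ``theta = 4`` by default.  ``scale = 0`` collapses both weights to 1.

DIoU and CIoU are included as plain comparison baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Box",
    "ShapeIoUParams",
    "ShapeIoUBreakdown",
    "iou",
    "iou_matrix",
    "shape_weights",
    "shape_distance",
    "shape_omega",
    "shape_iou_loss",
    "diou_loss",
    "ciou_loss",
    "convert_box",
]


@dataclass(frozen=True)
class Box:
    """Center-parameterized axis-aligned box: center (cx, cy), width w, height h."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"Box.{name} must be finite, got {v!r}")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"Box requires w > 0 and h > 0, got w={self.w}, h={self.h}")

    @property
    def x1(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def y1(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def x2(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def y2(self) -> float:
        return self.cy + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    def to_tlwh(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.w, self.h)

    @staticmethod
    def from_tlwh(left: float, top: float, w: float, h: float) -> "Box":
        return Box(left + w / 2.0, top + h / 2.0, w, h)


@dataclass(frozen=True)
class ShapeIoUParams:
    """Parameters of the Shape-IoU loss: dataset scale exponent and theta."""

    scale: float = 0.0
    theta: float = 4.0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


@dataclass(frozen=True)
class ShapeIoUBreakdown:
    """Per-term decomposition of one Shape-IoU loss evaluation."""

    iou: float
    distance_shape: float
    omega_shape: float
    ww: float
    hh: float
    loss: float


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 iff identical."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    # guard against round-off pushing the ratio a hair past 1
    return min(inter / (a.area + b.area - inter), 1.0)


def iou_matrix(a_tlwh: np.ndarray, b_tlwh: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two sets of boxes in (left, top, w, h) rows.

    Returns an ``(len(a), len(b))`` matrix; vectorized for use in the
    association and evaluation hot loops.
    """
    a = np.asarray(a_tlwh, dtype=float).reshape(-1, 4)
    b = np.asarray(b_tlwh, dtype=float).reshape(-1, 4)
    ax1, ay1 = a[:, 0], a[:, 1]
    ax2, ay2 = a[:, 0] + a[:, 2], a[:, 1] + a[:, 3]
    bx1, by1 = b[:, 0], b[:, 1]
    bx2, by2 = b[:, 0] + b[:, 2], b[:, 1] + b[:, 3]
    ix = np.minimum(ax2[:, None], bx2[None, :]) - np.maximum(ax1[:, None], bx1[None, :])
    iy = np.minimum(ay2[:, None], by2[None, :]) - np.maximum(ay1[:, None], by1[None, :])
    inter = np.clip(ix, 0.0, None) * np.clip(iy, 0.0, None)
    area_a = (a[:, 2] * a[:, 3])[:, None]
    area_b = (b[:, 2] * b[:, 3])[None, :]
    union = area_a + area_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return np.clip(out, 0.0, 1.0)


def _enclosing_diagonal_sq(a: Box, b: Box) -> float:
    cw = max(a.x2, b.x2) - min(a.x1, b.x1)
    ch = max(a.y2, b.y2) - min(a.y1, b.y1)
    return cw * cw + ch * ch


def shape_weights(gt: Box, scale: float) -> tuple[float, float]:
    """Horizontal/vertical weight coefficients (ww, hh) from the GT box shape.

    ww = 2 (w_gt)^scale / ((w_gt)^scale + (h_gt)^scale) and symmetrically for
    hh, so ww + hh == 2 always; scale = 0 or a square GT box gives (1, 1).
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    ws = gt.w**scale
    hs = gt.h**scale
    denom = ws + hs
    return 2.0 * ws / denom, 2.0 * hs / denom


def shape_distance(pred: Box, gt: Box, scale: float = 0.0) -> float:
    """Shape-weighted normalized squared center distance.

    distance = hh * (dx/c)^2 + ww * (dy/c)^2, where c is the diagonal of the
    minimal box enclosing both operands.  Note the cross-weighting: the x
    offset is weighted by hh and the y offset by ww.
    """
    ww, hh = shape_weights(gt, scale)
    c_sq = _enclosing_diagonal_sq(pred, gt)
    dx = pred.cx - gt.cx
    dy = pred.cy - gt.cy
    return hh * dx * dx / c_sq + ww * dy * dy / c_sq


def shape_omega(pred: Box, gt: Box, scale: float = 0.0, theta: float = 4.0) -> float:
    """Shape-discrepancy term Omega = sum_t (1 - e^{-omega_t})^theta.

    omega_w = hh * |w - w_gt| / max(w, w_gt) and omega_h = ww * |h - h_gt| /
    max(h, h_gt); zero iff the two boxes have identical width and height.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    ww, hh = shape_weights(gt, scale)
    omega_w = hh * abs(pred.w - gt.w) / max(pred.w, gt.w)
    omega_h = ww * abs(pred.h - gt.h) / max(pred.h, gt.h)
    return (1.0 - math.exp(-omega_w)) ** theta + (1.0 - math.exp(-omega_h)) ** theta


def shape_iou_loss(pred: Box, gt: Box, params: ShapeIoUParams | None = None) -> ShapeIoUBreakdown:
    """Shape-IoU loss of a predicted box against a ground-truth box.

    Returns the full per-term breakdown; ``loss = 1 - iou + distance_shape +
    omega_shape / 2`` holds exactly by construction.
    """
    p = params or ShapeIoUParams()
    ww, hh = shape_weights(gt, p.scale)
    i = iou(pred, gt)
    d = shape_distance(pred, gt, p.scale)
    om = shape_omega(pred, gt, p.scale, p.theta)
    return ShapeIoUBreakdown(
        iou=i, distance_shape=d, omega_shape=om, ww=ww, hh=hh,
        loss=1.0 - i + d + om / 2.0,
    )


def diou_loss(pred: Box, gt: Box) -> float:
    """Distance-IoU loss: 1 - IoU + d^2/c^2 (comparison baseline)."""
    c_sq = _enclosing_diagonal_sq(pred, gt)
    d_sq = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    return 1.0 - iou(pred, gt) + d_sq / c_sq


def ciou_loss(pred: Box, gt: Box) -> float:
    """Complete-IoU loss: DIoU plus an aspect-ratio consistency penalty."""
    i = iou(pred, gt)
    c_sq = _enclosing_diagonal_sq(pred, gt)
    d_sq = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    v = (4.0 / math.pi**2) * (math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)) ** 2
    alpha = 0.0 if v == 0.0 else v / (1.0 - i + v)
    return 1.0 - i + d_sq / c_sq + alpha * v


_CONVENTIONS = ("center", "tlwh", "corners", "yolo")


def convert_box(
    box,
    from_convention: str,
    to_convention: str,
    image_size: tuple[int, int] | None = None,
):
    """Convert a box between coordinate conventions.

    Conventions: ``center`` (cx, cy, w, h in px), ``tlwh`` (left, top, w, h),
    ``corners`` (x1, y1, x2, y2), ``yolo`` (cx, cy, w, h normalized to [0, 1];
    requires ``image_size = (width, height)``).  Accepts a Box or a 4-tuple;
    returns a Box for ``center`` targets and a tuple otherwise.
    """
    for name in (from_convention, to_convention):
        if name not in _CONVENTIONS:
            raise ValueError(f"unknown box convention {name!r}; expected one of {_CONVENTIONS}")
    if "yolo" in (from_convention, to_convention) and image_size is None:
        raise ValueError("image_size=(width, height) is required for YOLO-normalized conversions")

    if isinstance(box, Box):
        vals = (box.cx, box.cy, box.w, box.h)
        from_convention = "center"
    else:
        vals = tuple(float(v) for v in box)
        if len(vals) != 4:
            raise ValueError("box must have exactly 4 components")

    # normalize to center-pixel form
    if from_convention == "center":
        cx, cy, w, h = vals
    elif from_convention == "tlwh":
        left, top, w, h = vals
        cx, cy = left + w / 2.0, top + h / 2.0
    elif from_convention == "corners":
        x1, y1, x2, y2 = vals
        cx, cy, w, h = (x1 + x2) / 2.0, (y1 + y2) / 2.0, x2 - x1, y2 - y1
    else:  # yolo
        iw, ih = image_size
        cx, cy, w, h = vals[0] * iw, vals[1] * ih, vals[2] * iw, vals[3] * ih

    if to_convention == "center":
        return Box(cx, cy, w, h)
    if to_convention == "tlwh":
        return (cx - w / 2.0, cy - h / 2.0, w, h)
    if to_convention == "corners":
        return (cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)
    iw, ih = image_size
    return (cx / iw, cy / ih, w / iw, h / ih)
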