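"""Cobb-angle computation from segmented vertebrae.

The clinical Cobb angle is the angle between the upper endplate of the
uppermost involved vertebra and the lower endplate of the lowest involved
vertebra.  Here each segmented vertebra is reduced to its minimum-area
bounding rectangle (MBR); the rectangle's top and bottom edges stand in
for the endplates, and the curvature is

    phi = max_{a,b} arctan| (m_a - m_b) / (1 + m_a m_b) |,   b - a >= 2,

the maximum over all vertebra pairs at least one vertebra apart, where
``m_a`` is the upper-border slope of the upper vertebra and ``m_b`` the
lower-border slope of the lower vertebra.  Slopes are in the y-up frame
(see :mod:`spinecurve.image`).  The sign convention follows clinical
reading of AP films: ``phi < 0`` when the curve bends rightward, which is
the case when the maximising upper slope is below the lower slope.

Severity grading on |phi|: [0, 10) spinal curve, [10, 20) mild scoliosis,
[20, 40] moderate, above 40 severe (lower bound inclusive in each band).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .image import SpineImage

__all__ = [
    "MBR",
    "CobbResult",
    "min_bounding_rect",
    "endplate_slopes",
    "cobb_angle",
    "severity",
    "vertebra_label",
    "measure_spine",
]

#: T1..T12 then L1..L5, top to bottom.
VERTEBRA_LABELS = [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)]


def vertebra_label(index: int, n_vertebrae: int = 17) -> str:
    """0-based top-to-bottom index -> anatomical label (T1..L5 for 17)."""
    if n_vertebrae == 17 and 0 <= index < 17:
        return VERTEBRA_LABELS[index]
    return f"V{index + 1}"


@dataclass
class MBR:
    """Minimum-area enclosing rectangle of a vertebra mask.

    ``corners`` are four (row, col) points in order around the rectangle.
    ``upper_slope``/``lower_slope`` are the y-up slopes of the top and
    bottom edges; for a rectangle the two are equal.
    """

    corners: np.ndarray  # (4, 2) as (row, col)
    upper_slope: float
    lower_slope: float
    angle_of_long_axis: float  # degrees from the +x axis, in (-90, 90]
    area: float
    centroid: tuple[float, float]  # (row, col)
    touches_border: bool = False


def _rect_from_hull(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Edge-aligned rotating search for the minimum-area rectangle.

    The minimum-area enclosing rectangle of a convex polygon has one side
    collinear with a polygon edge, so trying every hull edge orientation
    is exact.  ``xy`` is (n, 2) Cartesian; returns (4, 2) corners and area.
    """
    try:
        hull = ConvexHull(xy)
        pts = xy[hull.vertices]
    except QhullError:  # collinear / tiny masks
        pts = xy
    edges = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 1e-12
    if not np.any(keep):  # single point
        c = pts[0]
        return np.tile(c, (4, 1)), 0.0
    units = edges[keep] / lengths[keep, None]
    best: tuple[float, np.ndarray] | None = None
    for ux, uy in units:
        # rotate points into the edge frame
        u = np.array([[ux, uy], [-uy, ux]])
        proj = pts @ u.T
        lo, hi = proj.min(axis=0), proj.max(axis=0)
        area = float((hi[0] - lo[0]) * (hi[1] - lo[1]))
        if best is None or area < best[0] - 1e-12:
            rect_frame = np.array(
                [[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]]
            )
            best = (area, rect_frame @ u)
    return best[1], best[0]


def min_bounding_rect(mask: np.ndarray) -> MBR:
    """Minimum-area bounding rectangle of a binary mask.

    Works on the convex hull of the mask's boundary pixels.  The two
    rectangle edges whose outward normal is closest to vertical are
    labelled top/bottom; their common slope provides the endplate slopes.
    """
    mask = np.asarray(mask).astype(bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask has no bounding rectangle")
    touches = bool(
        rows.min() == 0
        or cols.min() == 0
        or rows.max() == mask.shape[0] - 1
        or cols.max() == mask.shape[1] - 1
    )
    if touches:
        warnings.warn("mask touches the chip border; vertebra may be truncated")
    # boundary pixels only: cheaper hull, same rectangle
    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1] = (
        mask[1:-1, 1:-1]
        & mask[:-2, 1:-1]
        & mask[2:, 1:-1]
        & mask[1:-1, :-2]
        & mask[1:-1, 2:]
    )
    br, bc = np.nonzero(mask & ~interior)
    xy = np.column_stack([bc.astype(float), -br.astype(float)])  # y-up
    corners_xy, area = _rect_from_hull(xy)
    # classify edges: top/bottom are those with the most-vertical normal
    e = np.diff(np.vstack([corners_xy, corners_xy[:1]]), axis=0)
    elen = np.hypot(e[:, 0], e[:, 1])
    elen[elen == 0] = 1.0
    horizontality = np.abs(e[:, 0]) / elen  # |cos| of edge vs x-axis
    top_bot = np.argsort(horizontality)[-2:]  # two most horizontal edges
    # slope of those (parallel) edges
    ei = e[top_bot[0]]
    m = float(ei[1] / ei[0]) if abs(ei[0]) > 1e-12 else math.inf
    long_i = int(np.argmax(elen))
    ang = math.degrees(math.atan2(e[long_i, 1], e[long_i, 0]))
    if ang <= -90:
        ang += 180.0
    elif ang > 90:
        ang -= 180.0
    corners_rc = np.column_stack([-corners_xy[:, 1], corners_xy[:, 0]])
    centroid = (float(rows.mean()), float(cols.mean()))
    return MBR(
        corners=corners_rc,
        upper_slope=m,
        lower_slope=m,
        angle_of_long_axis=ang,
        area=area,
        centroid=centroid,
        touches_border=touches,
    )


def endplate_slopes(mbrs: Sequence[MBR]) -> tuple[np.ndarray, np.ndarray]:
    """Upper/lower endplate slope lists from top-to-bottom ordered MBRs."""
    if len(mbrs) < 3:
        raise ValueError("need at least 3 vertebrae for a Cobb angle")
    crows = [m.centroid[0] for m in mbrs]
    if any(b <= a for a, b in zip(crows, crows[1:])):
        raise ValueError("MBRs must be ordered top to bottom")
    upper = np.array([m.upper_slope for m in mbrs], dtype=float)
    lower = np.array([m.lower_slope for m in mbrs], dtype=float)
    return upper, lower


@dataclass
class CobbResult:
    """Signed Cobb angle with its end vertebrae and severity grade."""

    phi: float  # signed degrees; negative = curve bends rightward
    upper_index: int  # 0-based index of the upper end vertebra
    lower_index: int  # 0-based, lower end vertebra; lower - upper >= 2
    severity: str
    n_vertebrae: int
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def upper_label(self) -> str:
        return vertebra_label(self.upper_index, self.n_vertebrae)

    @property
    def lower_label(self) -> str:
        return vertebra_label(self.lower_index, self.n_vertebrae)


def cobb_angle(
    upper_slopes: Sequence[float],
    lower_slopes: Sequence[float],
    n_vertebrae: int | None = None,
) -> CobbResult:
    """Maximum curvature over all admissible vertebra pairs.

    Evaluates arctan|(m_i - m_j)/(1 + m_i m_j)| for every pair (i, j)
    with j - i >= 2 and keeps the maximum; ties go to the smallest
    (i, j).  Pairs with perpendicular endplates (1 + m_i m_j = 0) are
    skipped with a warning since their tangent quotient is undefined.
    """
    mu = np.asarray(upper_slopes, dtype=float)
    ml = np.asarray(lower_slopes, dtype=float)
    n = n_vertebrae if n_vertebrae is not None else len(mu)
    if len(mu) != len(ml) or len(mu) != n:
        raise ValueError("slope lists must both have length n_vertebrae")
    if n < 3:
        raise ValueError("Cobb angle needs at least 3 vertebrae (b - a >= 2)")
    best_ang = -1.0
    best_pair: tuple[int, int] | None = None
    best_sign = 1.0
    for i in range(n):
        for j in range(i + 2, n):
            denom = 1.0 + mu[i] * ml[j]
            if abs(denom) < 1e-12:
                warnings.warn(f"skipping perpendicular endplate pair ({i}, {j})")
                continue
            ang = math.degrees(math.atan(abs((mu[i] - ml[j]) / denom)))
            if ang > best_ang + 1e-12:
                best_ang = ang
                best_pair = (i, j)
                best_sign = -1.0 if mu[i] < ml[j] else 1.0
    if best_pair is None:
        raise ValueError("no admissible vertebra pair")
    phi = best_sign * best_ang
    return CobbResult(
        phi=phi,
        upper_index=best_pair[0],
        lower_index=best_pair[1],
        severity=severity(phi),
        n_vertebrae=n,
    )


def severity(phi: float) -> str:
    """Clinical grade from the Cobb magnitude (sign-invariant)."""
    a = abs(float(phi))
    if not math.isfinite(a):
        raise ValueError("Cobb angle must be finite")
    if a < 10.0:
        return "spinal curve"
    if a < 20.0:
        return "mild"
    if a <= 40.0:
        return "moderate"
    return "severe"


def measure_spine(
    image: SpineImage | np.ndarray,
    segmenter: str = "classical",
    network=None,
    window_params=None,
    expected_vertebrae: int = 17,
    probability_threshold: float = 0.5,
) -> CobbResult:
    """Full pipeline: ROI isolation -> detection -> segmentation -> Cobb.

    ``segmenter`` is ``"classical"`` (training-free threshold segmenter)
    or ``"network"`` with a trained model passed in ``network``.  The
    returned result carries per-stage artifacts (ROI box, vertebra boxes,
    masks, slopes) in ``extras``.
    """
    from . import detect as _detect
    from . import roi as _roi
    from . import segmentation as _seg

    if isinstance(image, np.ndarray):
        image = SpineImage(image)
    box, crop = _roi.isolate_spine_roi(image)
    params = window_params or _detect.WindowParams()
    chip_shape = (network.spec.input_shape if network is not None
                  else _detect.CHIP_SHAPE)
    boxes = _detect.detect_vertebrae(crop, params, expected_count=expected_vertebrae,
                                     chip_shape=chip_shape)
    if len(boxes) < 3:
        raise RuntimeError(
            f"only {len(boxes)} vertebrae detected; Cobb angle needs at least 3 "
            f"(ROI box {box.as_dict()})"
        )
    mbrs = []
    for vb in boxes:
        if segmenter == "classical":
            mask = _seg.classical_segment(vb.chip)
        elif segmenter == "network":
            if network is None:
                raise ValueError("segmenter='network' requires a trained network")
            mask = _seg.predict_mask(network, vb.chip, threshold=probability_threshold)
        else:
            raise ValueError(f"unknown segmenter {segmenter!r}")
        if not mask.any():
            continue
        # the anisotropic chip rescale shears tilted shapes, so the MBR is
        # computed after mapping the mask back to the isotropic ROI frame
        roi_mask = vb.mask_to_roi(mask)
        if not roi_mask.any():
            continue
        m = min_bounding_rect(roi_mask)
        crow = vb.chip_row0 + m.centroid[0]
        mbrs.append((crow, m.upper_slope, m.lower_slope, m, vb))
    if len(mbrs) < 3:
        raise RuntimeError(f"only {len(mbrs)} vertebrae segmented; need at least 3")
    mbrs.sort(key=lambda t: t[0])
    upper = np.array([t[1] for t in mbrs])
    lower = np.array([t[2] for t in mbrs])
    result = cobb_angle(upper, lower, len(mbrs))
    result.extras = {
        "roi_box": box.as_dict(),
        "n_detected": len(boxes),
        "n_segmented": len(mbrs),
        "upper_slopes": upper.tolist(),
        "lower_slopes": lower.tolist(),
        "vertebra_boxes": [t[4].as_dict() for t in mbrs],
        "mbr_corners_chip": [t[3].corners.tolist() for t in mbrs],
        "segmenter": segmenter,
    }
    return result
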