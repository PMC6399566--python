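"""Vertebra localisation in the spine ROI by projection voting.

Works on the quarter-scale ROI crop.  Four steps:

1.  *Central line segments* (CLS): H x W windows slide along the top of
    the ROI; the maximum-intensity-sum window seeds the first reference
    point (its top-middle), then the window steps down p rows, searches
    +-q columns, and repeats until n points form a segment, which is fit
    with a low-order polynomial col = f(row).  Segments chain (each new
    one seeded at the previous final window) until the ROI bottom.
2.  *Spine boundaries*: a pair of 11 x 5 sibling windows slides up to r
    pixels along the local CLS normal on each side; the position with
    the maximum inter-window intensity difference marks the boundary.
    Each side's points are fit with a degree-3 polynomial.
3.  *Central spinal curve* (CSC): the per-row midpoint of the two
    boundary polynomials.
4.  *Progressive-threshold voting*: the spine foreground between the
    boundaries is split into three equal-width column bands per row;
    the outer two are thresholded at gamma_t = 16 t for t = 1..15, the
    surviving pixels are projected onto the nearest CSC sample, and the
    binarised complements f_t(y) = [p_t(y) == 0] accumulate into the
    vote histogram P(y) = sum_t f_t(y).  Intervertebral discs are dark,
    so disc bins collect many votes while vertebral bins stay near zero;
    sharp rises of P mark vertebra/disc borders and a 15-bin
    sub-histogram scan converts them into horizontal cuts bounding each
    vertebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.transform import resize as _resize

from .image import SpineImage

__all__ = [
    "WindowParams",
    "CentralLineSegment",
    "BoundaryCurve",
    "CSCLine",
    "VoteHistogram",
    "VertebraBox",
    "find_reference_points",
    "trace_boundaries",
    "build_csc",
    "progressive_threshold",
    "locate_vertebrae",
    "detect_vertebrae",
]

CHIP_SHAPE = (256, 128)


@dataclass
class WindowParams:
    """Sliding-window parameters for CLS tracing and boundary search.

    Defaults follow the reference operating point: H=51, W=13, p=12,
    q=10, r=40, n=6 with 11x5 sibling windows, tuned for vertebrae that
    appear roughly 50 px tall on the quarter-scale image.
    """

    H: int = 51
    W: int = 13
    p: int = 12
    q: int = 10
    r: int = 40
    n: int = 6
    sibling_h: int = 11
    sibling_w: int = 5
    cls_degree: int = 2
    boundary_degree: int = 3
    vote_thresholds: int = 15  # t = 1..15, gamma_t = 16 t
    gamma_step: float = 16.0
    subhist_bins: int = 15
    rise_threshold: int = 8  # "drastic change" of the vote histogram
    rise_window: int = 6  # bins over which the rise may accumulate

    def __post_init__(self) -> None:
        for name in ("H", "W", "p", "q", "r", "n", "sibling_h", "sibling_w"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.W % 2 == 0:
            raise ValueError("W must be odd so the window has a top-middle pixel")


@dataclass
class CentralLineSegment:
    reference_points: np.ndarray  # (n, 2) as (row, col), rows strictly increasing
    poly_coeffs: np.ndarray  # col = polyval(coeffs, row)

    def __post_init__(self) -> None:
        rp = np.asarray(self.reference_points, dtype=float)
        if np.any(np.diff(rp[:, 0]) <= 0):
            raise ValueError("reference rows must be strictly increasing")
        self.reference_points = rp


@dataclass
class BoundaryCurve:
    side: str  # "left" | "right"
    points: np.ndarray  # (m, 2) as (row, col)
    poly_coeffs: np.ndarray  # degree-3, col = polyval(coeffs, row)

    def __call__(self, rows: np.ndarray) -> np.ndarray:
        return np.polyval(self.poly_coeffs, rows)


@dataclass
class CSCLine:
    points: np.ndarray  # (beta, 2) as (row, col) midpoints

    @property
    def beta(self) -> int:
        return len(self.points)


@dataclass
class VoteHistogram:
    p_t: np.ndarray  # (15, beta) raw projection counts per threshold
    f_t: np.ndarray  # (15, beta) binarised complements, values in {0, 1}
    P: np.ndarray  # (beta,) accumulated votes

    def __post_init__(self) -> None:
        # vote identities hold on every construction, not just in tests
        assert np.isin(self.f_t, (0, 1)).all(), "f_t must be binary"
        assert np.array_equal(self.f_t, (self.p_t == 0).astype(int))
        assert np.array_equal(self.P, self.f_t.sum(axis=0))
        assert self.P.min() >= 0 and self.P.max() <= self.f_t.shape[0]


@dataclass
class VertebraBox:
    """One detected vertebra in ROI coordinates, with its rescaled chip.

    The box rows come from consecutive vote-histogram cuts and never
    overlap the neighbouring boxes; the chip is cropped with a small
    contextual margin around the box (tilted vertebra corners extend
    past the horizontal cuts), so the chip's crop origin and scales are
    recorded for mapping chip measurements back to ROI coordinates.
    """

    index: int  # 0-based, top to bottom
    upper_row: int
    lower_row: int  # exclusive
    left: int
    right: int  # exclusive
    chip: np.ndarray  # chip_shape crop of the ROI image
    chip_row0: int = 0  # ROI row of the chip crop's first row
    chip_col0: int = 0
    crop_shape: tuple[int, int] = (0, 0)  # pre-rescale crop size in ROI px
    row_scale: float = 1.0  # chip rows per ROI row
    col_scale: float = 1.0  # chip cols per ROI col

    def mask_to_roi(self, mask: np.ndarray) -> np.ndarray:
        """Map a chip-space binary mask back to the ROI-space crop.

        The 256x128 chip rescale is anisotropic and shears any tilted
        shape, so measurements that depend on angles (the minimum
        bounding rectangle in particular) must be taken after mapping
        the mask back to the isotropic ROI frame.
        """
        return _resize(np.asarray(mask, dtype=float), self.crop_shape,
                       order=0, preserve_range=True, anti_aliasing=False) > 0.5

    def as_dict(self) -> dict:
        return {
            "index": self.index,
            "upper_row": self.upper_row,
            "lower_row": self.lower_row,
            "left": self.left,
            "right": self.right,
        }


def _window_sums(integral: np.ndarray, tops: np.ndarray, lefts: np.ndarray,
                 h: int, w: int) -> np.ndarray:
    """Sums of h x w windows at (top, left) positions via an integral image."""
    t, l = tops, lefts
    return (integral[t + h, l + w] - integral[t, l + w]
            - integral[t + h, l] + integral[t, l])


def _integral(px: np.ndarray) -> np.ndarray:
    out = np.zeros((px.shape[0] + 1, px.shape[1] + 1))
    np.cumsum(np.cumsum(px, axis=0), axis=1, out=out[1:, 1:])
    return out


def find_reference_points(
    roi_image: SpineImage | np.ndarray,
    params: WindowParams | None = None,
    start_row: int = 0,
    start_col: int | None = None,
) -> CentralLineSegment:
    """One CLS: n max-intensity window points stepping down p rows.

    The first point comes from an exhaustive scan along ``start_row``
    (full width when ``start_col`` is None, else +-q around it); each
    later point searches +-q columns around its predecessor.  Ties go to
    the leftmost window.
    """
    params = params or WindowParams()
    px = roi_image.pixels if isinstance(roi_image, SpineImage) else np.asarray(roi_image, dtype=float)
    Hh, Ww = px.shape
    if Ww < params.W:
        raise ValueError(f"ROI width {Ww} narrower than window W={params.W}")
    if Hh < start_row + params.H:
        raise ValueError(f"ROI height {Hh} too small for H={params.H} at row {start_row}")
    integ = _integral(px)
    half = params.W // 2
    points = []
    row = start_row
    col = start_col  # column of the window's top-middle point
    for _ in range(params.n):
        if row + params.H > Hh:
            break
        if col is None:
            lefts = np.arange(0, Ww - params.W + 1)
        else:
            lo = max(0, col - half - params.q)
            hi = min(Ww - params.W, col - half + params.q)
            if hi < lo:
                lo = hi = min(max(col - half, 0), Ww - params.W)
            lefts = np.arange(lo, hi + 1)
        sums = _window_sums(integ, np.full(len(lefts), row), lefts, params.H, params.W)
        best = int(lefts[np.argmax(sums)])  # argmax takes the first = leftmost tie
        col = best + half
        points.append((row, col))
        row += params.p
    pts = np.array(points, dtype=float)
    deg = min(params.cls_degree, len(pts) - 1)
    coeffs = np.polyfit(pts[:, 0], pts[:, 1], deg)
    # single robust refit: a reference point that jumped onto a noise
    # ridge would otherwise swing the local polynomial (and with it every
    # boundary normal of the segment)
    if len(pts) >= 4:
        resid = np.abs(np.polyval(coeffs, pts[:, 0]) - pts[:, 1])
        scale = np.median(resid) + 1e-9
        keep = resid <= max(4.0, 3.0 * scale)
        if keep.sum() >= deg + 1 and not keep.all():
            coeffs = np.polyfit(pts[keep, 0], pts[keep, 1], deg)
    return CentralLineSegment(pts, coeffs)


def _chain_segments(px: np.ndarray, params: WindowParams) -> list[CentralLineSegment]:
    """CLS segments chained down the ROI, each seeded at its predecessor's end."""
    segments = []
    row, col = 0, None
    Hh = px.shape[0]
    img = SpineImage(px)
    while row + params.H <= Hh:
        seg = find_reference_points(img, params, start_row=row, start_col=col)
        segments.append(seg)
        last_row, last_col = seg.reference_points[-1]
        row = int(last_row) + params.p
        col = int(last_col)
        if len(seg.reference_points) < 2:
            break
    return segments


def trace_boundaries(
    roi_image: SpineImage | np.ndarray,
    params: WindowParams | None = None,
) -> tuple[BoundaryCurve, BoundaryCurve]:
    """Left/right spine boundary curves via sibling-window edge search.

    For every integer row covered by the chained CLS segments, a pair of
    sibling windows slides outward up to r px along the local normal;
    the split position with the maximum absolute intensity difference
    between the two windows is the boundary point.  Each side's points
    are fitted with one degree-3 polynomial over the full ROI height.
    """
    params = params or WindowParams()
    px = roi_image.pixels if isinstance(roi_image, SpineImage) else np.asarray(roi_image, dtype=float)
    Hh, Ww = px.shape
    segments = _chain_segments(px, params)
    if not segments:
        raise ValueError("ROI too small to trace a central line segment")
    integ = _integral(px)
    sh, sw = params.sibling_h, params.sibling_w
    left_pts, right_pts = [], []
    for seg in segments:
        r0 = int(seg.reference_points[0, 0])
        r1 = int(seg.reference_points[-1, 0]) + params.p
        r1 = min(r1, Hh)
        dpoly = np.polyder(seg.poly_coeffs)
        for row in range(r0, r1):
            c = float(np.polyval(seg.poly_coeffs, row))
            slope = float(np.polyval(dpoly, row)) if len(seg.poly_coeffs) > 1 else 0.0
            if not np.isfinite(slope):
                warnings.warn("degenerate CLS tangent; using horizontal normal")
                slope = 0.0
            # normal to the (down, slope) tangent, unit length
            norm = np.array([-slope, 1.0]) / np.hypot(slope, 1.0)  # (drow, dcol)
            for sign, acc in ((-1.0, left_pts), (1.0, right_pts)):
                # candidate split positions stepping outward along the normal;
                # the sibling windows sit immediately either side of the split
                steps = np.arange(0, params.r + 1, dtype=float)
                rr = row + sign * steps * norm[0]
                cc = c + sign * steps * norm[1]
                ti = np.round(rr - sh / 2).astype(int)
                la = np.round(cc - sw).astype(int)  # window just before the split
                lb = np.round(cc).astype(int)  # window just after
                ok = (ti >= 0) & (ti + sh <= Hh) & (la >= 0) & (lb + sw <= Ww)
                if not ok.any():
                    continue
                s_a = _window_sums(integ, ti[ok], la[ok], sh, sw)
                s_b = _window_sums(integ, ti[ok], lb[ok], sh, sw)
                diffs = np.abs(s_a - s_b)
                idx = np.nonzero(ok)[0][int(np.argmax(diffs))]
                # window rounding lands the split on the first pixel past
                # the edge; half a pixel outward centres it on the edge
                acc.append((row, float(cc[idx]) + 0.5 * sign))
    if not left_pts or not right_pts:
        raise ValueError("boundary search found no valid window positions")
    def _robust_fit(pts: np.ndarray) -> np.ndarray:
        deg = min(params.boundary_degree, len(pts) - 1)
        coeffs = np.polyfit(pts[:, 0], pts[:, 1], deg)
        # one rejection pass: disc rows have weak edges and throw a
        # minority of points far off the cortical margin
        resid = np.abs(np.polyval(coeffs, pts[:, 0]) - pts[:, 1])
        scale = np.median(resid) + 1e-9
        keep = resid <= max(3.0, 3.0 * scale)
        if keep.sum() > deg + 1 and not keep.all():
            coeffs = np.polyfit(pts[keep, 0], pts[keep, 1], deg)
        return coeffs

    lp = np.array(left_pts)
    rp = np.array(right_pts)
    return (BoundaryCurve("left", lp, _robust_fit(lp)),
            BoundaryCurve("right", rp, _robust_fit(rp)))


def build_csc(left: BoundaryCurve, right: BoundaryCurve,
              rows: np.ndarray | None = None) -> CSCLine:
    """Central spinal curve: per-row midpoints of the boundary pair."""
    if rows is None:
        r0 = int(max(left.points[:, 0].min(), right.points[:, 0].min()))
        r1 = int(min(left.points[:, 0].max(), right.points[:, 0].max()))
        rows = np.arange(r0, r1 + 1)
    lv = left(rows)
    rv = right(rows)
    crossing = lv > rv
    if crossing.any():
        raise ValueError(
            f"boundary curves cross at row {int(rows[crossing][0])}"
        )
    mid = (lv + rv) / 2.0
    return CSCLine(np.column_stack([rows, mid]))


def progressive_threshold(
    roi_image: SpineImage | np.ndarray,
    csc: CSCLine,
    boundaries: tuple[BoundaryCurve, BoundaryCurve],
    params: WindowParams | None = None,
) -> VoteHistogram:
    """Vote histogram over CSC positions from the threshold ladder.

    Foreground pixels between the boundary curves are split row-wise into
    three equal-width bands; only the outer two vote.  For each t the
    pixels with intensity >= gamma_t are projected to their nearest CSC
    sample (perpendicular foot approximated by nearest point) and
    counted into p_t; f_t and P follow the binarise-and-accumulate rule.
    """
    params = params or WindowParams()
    px = roi_image.pixels if isinstance(roi_image, SpineImage) else np.asarray(roi_image, dtype=float)
    Hh, Ww = px.shape
    left, right = boundaries
    rows = csc.points[:, 0].astype(int)
    lv = np.clip(left(rows), 0, Ww - 1)
    rv = np.clip(right(rows), 0, Ww - 1)
    # gather foreground pixels in the outer thirds
    pix_rows, pix_cols, pix_vals = [], [], []
    for i, row in enumerate(rows):
        a, b = lv[i], rv[i]
        if b - a < 3:
            continue
        third = (b - a) / 3.0
        c0 = np.arange(int(np.ceil(a)), int(np.floor(a + third)) + 1)
        c2 = np.arange(int(np.ceil(b - third)), int(np.floor(b)) + 1)
        cols = np.concatenate([c0, c2])
        cols = cols[(cols >= 0) & (cols < Ww)]
        pix_rows.append(np.full(len(cols), row))
        pix_cols.append(cols)
        pix_vals.append(px[row, cols])
    if not pix_rows:
        raise ValueError("empty spine foreground between the boundary curves")
    pr = np.concatenate(pix_rows)
    pc = np.concatenate(pix_cols)
    pv = np.concatenate(pix_vals)
    # nearest CSC sample for every foreground pixel
    tree = cKDTree(csc.points)
    _, bin_idx = tree.query(np.column_stack([pr, pc]), k=1)
    beta = csc.beta
    T = params.vote_thresholds
    p_t = np.zeros((T, beta), dtype=int)
    for t in range(1, T + 1):
        gamma = params.gamma_step * t
        sel = pv >= gamma
        if sel.any():
            p_t[t - 1] = np.bincount(bin_idx[sel], minlength=beta)
    f_t = (p_t == 0).astype(int)
    P = f_t.sum(axis=0)
    return VoteHistogram(p_t=p_t, f_t=f_t, P=P)


def _starting_points(P: np.ndarray, theta: int, window: int) -> list[int]:
    """Indices where P rises by >= theta within a trailing window."""
    starts = []
    y = 1
    n = len(P)
    while y < n:
        lo = max(0, y - window)
        rise = P[y] - P[lo:y].min()
        if rise >= theta:
            start = lo + int(np.argmin(P[lo:y]))
            starts.append(start)
            # skip past this rising edge
            while y < n - 1 and P[y + 1] >= P[y]:
                y += 1
        y += 1
    return starts


def locate_vertebrae(
    votes: VoteHistogram,
    csc: CSCLine,
    boundaries: tuple[BoundaryCurve, BoundaryCurve],
    roi_image: SpineImage | np.ndarray | None = None,
    params: WindowParams | None = None,
    expected_count: int = 17,
    chip_shape: tuple[int, int] = CHIP_SHAPE,
    chip_margin: float = 0.15,
) -> list[VertebraBox]:
    """Vertebra boxes from the vote histogram.

    Each drastic rise of P seeds a 15-bin sub-histogram whose first
    global maximum marks a horizontal cut (a disc centre); consecutive
    cuts plus the boundary curves bound the vertebrae.  Cuts are
    complemented by the ROI top and bottom so end vertebrae are kept.
    Chips are cropped with ``chip_margin`` of the box size added on every
    side so tilted vertebra corners stay inside the crop.
    """
    params = params or WindowParams()
    P = votes.P
    beta = len(P)
    starts = _starting_points(P, params.rise_threshold, params.rise_window)
    cuts: list[int] = []
    last_cut = -params.subhist_bins
    for a in starts:
        if a < last_cut + 1:
            continue
        wnd = P[a : min(a + params.subhist_bins, beta)]
        if len(wnd) == 0:
            continue
        cut = a + int(np.argmax(wnd))  # first global maximum
        if cut - last_cut >= params.subhist_bins:
            cuts.append(cut)
            last_cut = cut
    if not cuts:
        warnings.warn("no drastic vote rises found; detection failed")
        return []
    edges = [0] + cuts + ([beta - 1] if beta - 1 - cuts[-1] >= params.subhist_bins else [])
    boxes: list[VertebraBox] = []
    rows = csc.points[:, 0]
    left, right = boundaries
    px = None
    if roi_image is not None:
        px = roi_image.pixels if isinstance(roi_image, SpineImage) else np.asarray(roi_image, dtype=float)
    for k, (e0, e1) in enumerate(zip(edges[:-1], edges[1:])):
        r0 = int(rows[e0])
        r1 = int(rows[min(e1, beta - 1)])
        if r1 - r0 < 3:
            continue
        # a vertebra interval must contain low-vote (bony) bins; an
        # interval that is all high votes is a bare disc/end region
        if P[e0 : e1 + 1].min() >= params.rise_threshold:
            continue
        seg_rows = np.arange(r0, r1)
        l = int(np.floor(left(seg_rows).min()))
        r = int(np.ceil(right(seg_rows).max())) + 1
        l = max(0, l)
        if px is not None:
            r = min(r, px.shape[1])
        if r - l < 3:
            continue
        chip = None
        row_scale = col_scale = 1.0
        cr0 = cl0 = 0
        if px is not None:
            mr = int(round(chip_margin * (r1 - r0)))
            mc = int(round(chip_margin * (r - l)))
            cr0, cr1 = max(0, r0 - mr), min(px.shape[0], r1 + mr)
            cl0, cl1 = max(0, l - mc), min(px.shape[1], r + mc)
            crop = px[cr0:cr1, cl0:cl1]
            chip = _resize(crop, chip_shape, order=1, preserve_range=True,
                           anti_aliasing=True).astype(np.float32)
            row_scale = chip_shape[0] / crop.shape[0]
            col_scale = chip_shape[1] / crop.shape[1]
        boxes.append(VertebraBox(index=len(boxes), upper_row=r0, lower_row=r1,
                                 left=l, right=r, chip=chip,
                                 chip_row0=cr0, chip_col0=cl0,
                                 crop_shape=crop.shape if px is not None else (0, 0),
                                 row_scale=row_scale, col_scale=col_scale))
    if len(boxes) != expected_count:
        warnings.warn(f"detected {len(boxes)} vertebrae, expected {expected_count}")
    return boxes


def detect_vertebrae(
    roi_image: SpineImage | np.ndarray,
    params: WindowParams | None = None,
    expected_count: int = 17,
    chip_shape: tuple[int, int] = CHIP_SHAPE,
) -> list[VertebraBox]:
    """Full detection stage: boundaries -> CSC -> votes -> boxes."""
    params = params or WindowParams()
    left, right = trace_boundaries(roi_image, params)
    csc = build_csc(left, right)
    votes = progressive_threshold(roi_image, csc, (left, right), params)
    return locate_vertebrae(votes, csc, (left, right), roi_image, params,
                            expected_count=expected_count, chip_shape=chip_shape)
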