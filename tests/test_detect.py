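"""Vertebra detection: CLS tracing, boundaries, votes and boxes."""

import warnings

import numpy as np
import pytest

from spinecurve.detect import (
    BoundaryCurve,
    CSCLine,
    VoteHistogram,
    WindowParams,
    build_csc,
    detect_vertebrae,
    find_reference_points,
    locate_vertebrae,
    progressive_threshold,
    trace_boundaries,
)
from spinecurve.image import SpineImage


def brute_force_first_window(px, H, W):
    """Oracle: exhaustive sum of every top-row window, leftmost max."""
    best = (-1.0, None)
    for left in range(px.shape[1] - W + 1):
        s = px[:H, left : left + W].sum()
        if s > best[0] + 1e-9:
            best = (s, left + W // 2)
    return best[1]


class TestReferencePoints:
    def test_bright_strip_centers_all_points(self):
        params = WindowParams()
        px = np.zeros((140, 80))
        px[:, 30:43] = 100.0  # exactly W=13 wide
        seg = find_reference_points(SpineImage(px), params)
        assert len(seg.reference_points) == params.n
        assert np.all(seg.reference_points[:, 1] == 36)

    def test_n_default_points_span_5p_rows(self):
        params = WindowParams()
        px = np.zeros((200, 60))
        px[:, 20:33] = 50.0
        seg = find_reference_points(SpineImage(px), params)
        rows = seg.reference_points[:, 0]
        assert rows[-1] - rows[0] == 5 * params.p == 60

    def test_tie_broken_to_leftmost(self):
        px = np.zeros((120, 100))
        px[:, 10:23] = 80.0
        px[:, 60:73] = 80.0  # identical second strip
        seg = find_reference_points(SpineImage(px), WindowParams())
        assert seg.reference_points[0, 1] == 16

    def test_matches_exhaustive_window_search(self, rng):
        params = WindowParams()
        for _ in range(10):
            px = rng.uniform(0, 255, size=(120, 90))
            seg = find_reference_points(SpineImage(px), params)
            assert seg.reference_points[0, 1] == brute_force_first_window(
                px, params.H, params.W
            )

    def test_too_narrow_roi_rejected(self):
        with pytest.raises(ValueError, match="narrower"):
            find_reference_points(SpineImage(np.zeros((100, 8))), WindowParams())


class TestBoundaries:
    def test_bright_rectangle_edges_recovered(self):
        px = np.full((160, 100), 10.0)
        px[:, 30:70] = 200.0  # width-40 bright band
        left, right = trace_boundaries(SpineImage(px), WindowParams())
        rows = np.arange(30, 130)
        assert np.abs(left(rows) - 30).mean() <= 1.5
        assert np.abs(right(rows) - 70).mean() <= 1.5

    def test_symmetric_image_gives_symmetric_offsets(self):
        px = np.full((160, 101), 10.0)
        px[:, 35:66] = 180.0  # symmetric about column 50
        left, right = trace_boundaries(SpineImage(px), WindowParams())
        rows = np.arange(40, 120)
        mid = (left(rows) + right(rows)) / 2
        assert np.abs(mid - 50).mean() < 2.0

    def test_phantom_boundary_error_within_2px(self, phantom20, roi20):
        box, crop = roi20
        left, right = trace_boundaries(crop, WindowParams())
        spec = phantom20.spec
        rows = np.arange(60, crop.height - 80)
        full_rows = (rows + box.top) * 4
        center = np.polyval(spec.centerline_coeffs, full_rows) / 4 - box.left
        half = spec.vertebra_width / 8.0
        assert np.abs(left(rows) - (center - half)).mean() <= 2.0
        assert np.abs(right(rows) - (center + half)).mean() <= 2.0


class TestCSC:
    def test_constant_boundaries_midpoint(self):
        rows = np.arange(0, 50)
        left = BoundaryCurve("left", np.column_stack([rows, np.full(50, 10.0)]), np.array([10.0]))
        right = BoundaryCurve("right", np.column_stack([rows, np.full(50, 30.0)]), np.array([30.0]))
        csc = build_csc(left, right)
        assert np.allclose(csc.points[:, 1], 20.0)
        assert csc.beta == 50

    def test_crossing_boundaries_name_the_row(self):
        rows = np.arange(0, 20)
        left = BoundaryCurve("left", np.column_stack([rows, np.full(20, 30.0)]), np.array([30.0]))
        right = BoundaryCurve("right", np.column_stack([rows, np.full(20, 10.0)]), np.array([10.0]))
        with pytest.raises(ValueError, match="cross"):
            build_csc(left, right)

    def test_phantom_csc_tracks_centerline(self, phantom20, roi20):
        box, crop = roi20
        left, right = trace_boundaries(crop, WindowParams())
        csc = build_csc(left, right)
        rows = csc.points[:, 0]
        keep = (rows > 60) & (rows < crop.height - 80)
        full_rows = (rows[keep] + box.top) * 4
        center = np.polyval(phantom20.spec.centerline_coeffs, full_rows) / 4 - box.left
        rms = np.sqrt(np.mean((csc.points[keep, 1] - center) ** 2))
        assert rms <= 2.0


def _flat_band_setup(level):
    """A uniform vertical band with straight boundaries for vote tests."""
    px = np.full((200, 90), 0.0)
    px[:, 25:65] = level
    rows = np.arange(0, 200)
    left = BoundaryCurve("left", np.column_stack([rows, np.full(200, 25.0)]), np.array([25.0]))
    right = BoundaryCurve("right", np.column_stack([rows, np.full(200, 65.0)]), np.array([65.0]))
    csc = build_csc(left, right)
    return SpineImage(px), csc, (left, right)


class TestVotes:
    def test_uniform_intensity_100_splits_at_t7(self):
        img, csc, bounds = _flat_band_setup(100.0)
        votes = progressive_threshold(img, csc, bounds)
        # gamma_t = 16 t: pixels at 100 survive thresholds t <= 6 (gamma <= 96)
        assert np.all(votes.f_t[:6] == 0)
        assert np.all(votes.f_t[6:] == 1)

    def test_vote_identities(self, phantom20, roi20):
        _, crop = roi20
        left, right = trace_boundaries(crop, WindowParams())
        csc = build_csc(left, right)
        votes = progressive_threshold(crop, csc, (left, right))
        assert np.isin(votes.f_t, (0, 1)).all()
        assert np.array_equal(votes.P, votes.f_t.sum(axis=0))
        assert votes.P.max() <= 15
        assert np.all((votes.p_t > 0) == (votes.f_t == 0))

    def test_inconsistent_histogram_rejected(self):
        p_t = np.zeros((15, 10), dtype=int)
        f_t = np.ones((15, 10), dtype=int)
        with pytest.raises(AssertionError):
            VoteHistogram(p_t=p_t, f_t=f_t, P=np.zeros(10, dtype=int))


def _synthetic_votes(P):
    beta = len(P)
    f_t = np.zeros((15, beta), dtype=int)
    # consistent f_t/p_t pair realising the requested P
    for y, v in enumerate(P):
        f_t[:v, y] = 1
    p_t = (f_t == 0).astype(int)
    rows = np.arange(beta)
    pts = np.column_stack([rows, np.full(beta, 20.0)])
    csc = CSCLine(pts)
    left = BoundaryCurve("left", np.column_stack([rows, np.full(beta, 5.0)]), np.array([5.0]))
    right = BoundaryCurve("right", np.column_stack([rows, np.full(beta, 35.0)]), np.array([35.0]))
    return VoteHistogram(p_t=p_t, f_t=f_t, P=np.asarray(P)), csc, (left, right)


class TestLocate:
    def test_alternating_blocks_cut_at_transitions(self):
        # 20-bin vertebrae (P=0) alternating with 20-bin discs (P=15)
        P = np.tile(np.concatenate([np.zeros(20, int), np.full(20, 15, int)]), 5)
        votes, csc, bounds = _synthetic_votes(P)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boxes = locate_vertebrae(votes, csc, bounds, expected_count=5)
        assert len(boxes) == 5
        # every vertebra block (vote minimum) is covered by exactly one box
        for start in (0, 40, 80, 120, 160):
            covering = [b for b in boxes if b.upper_row <= start + 10 < b.lower_row]
            assert len(covering) == 1

    def test_monotone_votes_fail_cleanly(self):
        P = np.linspace(0, 6, 120).astype(int)
        votes, csc, bounds = _synthetic_votes(P)
        with pytest.warns(UserWarning, match="detection failed"):
            boxes = locate_vertebrae(votes, csc, bounds, expected_count=17)
        assert boxes == []

    def test_phantom_detects_17_ordered_boxes(self, phantom20, boxes20):
        assert len(boxes20) == 17
        uppers = [b.upper_row for b in boxes20]
        assert uppers == sorted(uppers)
        lowers = [b.lower_row for b in boxes20]
        assert all(u >= l for u, l in zip(uppers[1:], lowers[:-1]))  # non-overlap

    def test_boxes_match_generative_vertebrae(self, phantom20, roi20, boxes20):
        box, _ = roi20
        cents = phantom20.centroids / 4.0
        hits = []
        for vb in boxes20:
            inside = np.where(
                (cents[:, 0] - box.top >= vb.upper_row)
                & (cents[:, 0] - box.top < vb.lower_row)
            )[0]
            assert len(inside) == 1
            hits.append(inside[0])
        assert hits == sorted(hits)

    def test_chips_have_requested_shape(self, boxes20):
        for vb in boxes20:
            assert vb.chip.shape == (256, 128)


class TestEndToEnd:
    def test_detect_vertebrae_composes(self, roi20):
        _, crop = roi20
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boxes = detect_vertebrae(crop, chip_shape=(64, 32))
        assert len(boxes) == 17
        assert boxes[0].chip.shape == (64, 32)

    def test_window_params_validation(self):
        with pytest.raises(ValueError, match="odd"):
            WindowParams(W=12)
        with pytest.raises(ValueError):
            WindowParams(H=0)
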