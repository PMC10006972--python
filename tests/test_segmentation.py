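"""Luminance, gradient, watershed flood and the two-stage pipeline."""

import datetime as dt

import numpy as np
import pytest

from conftest import iou
from flood_oracle import oracle_flood
from footcheck import (
    SceneParams,
    ScribbleSet,
    SegmentationError,
    Stroke,
    assess_quality,
    generate_scene,
    generate_scribbles,
    measure,
    morphological_gradient,
    segment_foot,
    segment_ulcer,
    to_luminance,
    validate_scribbles,
    watershed_flood,
)


class TestLuminance:
    @pytest.mark.parametrize("v", [0, 1, 77, 128, 254, 255])
    def test_grey_maps_to_itself(self, v):
        img = np.full((3, 3, 3), v, dtype=np.uint8)
        assert (to_luminance(img) == v).all()

    def test_pure_red_rounds_half_up(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[..., 0] = 255  # 0.299 * 255 = 76.245 -> 76
        assert to_luminance(img)[0, 0] == 76

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            to_luminance(np.zeros((4, 4), dtype=np.uint8))


def brute_gradient(grid):
    """Dilation minus erosion with a 3x3 cross, computed by explicit loops
    with edge replication."""
    grid = np.asarray(grid, int)
    h, w = grid.shape
    out = np.zeros_like(grid)
    for r in range(h):
        for c in range(w):
            vals = [grid[r, c]]
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr = min(max(r + dr, 0), h - 1)
                cc = min(max(c + dc, 0), w - 1)
                vals.append(grid[rr, cc])
            out[r, c] = max(vals) - min(vals)
    return out


class TestGradient:
    def test_flat_image_has_zero_gradient(self):
        assert not morphological_gradient(np.full((6, 6), 42)).any()

    def test_vertical_step_edge(self):
        grid = np.zeros((6, 6), int)
        grid[:, 3:] = 100
        grad = morphological_gradient(grid)
        assert np.array_equal(grad, brute_gradient(grid))
        assert (grad[:, 2:4] == 100).all()
        assert not grad[:, :2].any() and not grad[:, 4:].any()

    def test_single_bright_pixel_cross_support(self):
        grid = np.zeros((5, 5), int)
        grid[2, 2] = 50
        grad = morphological_gradient(grid)
        assert np.array_equal(grad, brute_gradient(grid))
        support = {(2, 2), (1, 2), (3, 2), (2, 1), (2, 3)}
        assert set(zip(*np.nonzero(grad))) == support


def random_instance(rng, h=16, w=16, n_labels=2, masked=False):
    gradient = rng.integers(0, 10, size=(h, w))
    markers = np.zeros((h, w), dtype=int)
    spots = rng.choice(h * w, size=n_labels, replace=False)
    for lab, flat in enumerate(spots, start=1):
        markers[flat // w, flat % w] = lab
    mask = None
    if masked:
        mask = np.ones((h, w), bool)
        mask[rng.random((h, w)) < 0.2] = False
        mask[markers > 0] = True
    return gradient, markers, mask


class TestWatershedFlood:
    def test_two_corner_markers_partition_whole_grid(self):
        gradient = np.zeros((4, 4), int)
        markers = np.zeros((4, 4), int)
        markers[0, 0] = 2
        markers[3, 3] = 1
        grid = watershed_flood(gradient, markers)
        expected = np.asarray(oracle_flood(gradient.tolist(), markers.tolist()))
        assert np.array_equal(grid.labels, expected)
        assert set(np.unique(grid.labels)) <= {0, 1, 2}
        assert (grid.labels != -1).all()  # every pixel labelled or on the line

    def test_one_dimensional_ridge_example(self):
        gradient = np.array([[0, 0, 1, 9, 1, 0, 0]])
        markers = np.array([[1, 0, 0, 0, 0, 0, 2]])
        grid = watershed_flood(gradient, markers)
        assert grid.labels.tolist() == [[1, 1, 1, 0, 2, 2, 2]]

    def test_single_marker_label_is_an_error(self):
        markers = np.zeros((4, 4), int)
        markers[1, 1] = 2
        with pytest.raises(SegmentationError):
            watershed_flood(np.zeros((4, 4), int), markers)

    @pytest.mark.parametrize("masked", [False, True])
    def test_matches_brute_force_oracle(self, masked):
        rng = np.random.default_rng(42)
        for _ in range(25):
            gradient, markers, mask = random_instance(
                rng, n_labels=int(rng.integers(2, 4)), masked=masked
            )
            grid = watershed_flood(gradient, markers, region_mask=mask)
            expected = np.asarray(
                oracle_flood(
                    gradient.tolist(),
                    markers.tolist(),
                    None if mask is None else mask.tolist(),
                )
            )
            assert np.array_equal(grid.labels, expected)

    def test_partition_conservation(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            gradient, markers, _ = random_instance(rng)
            grid = watershed_flood(gradient, markers)
            n1 = (grid.labels == 1).sum()
            n2 = (grid.labels == 2).sum()
            nline = (grid.labels == 0).sum()
            assert n1 + n2 + nline == gradient.size


class TestPipeline:
    def test_foot_mask_recovers_ground_truth(self, default_scene, default_scribbles):
        image, truth = default_scene
        result = segment_foot(image, default_scribbles)
        assert iou(result.foot_mask, truth.foot_mask) >= 0.99
        assert result.flags.ulcer_empty
        assert not result.flags.foot_touches_border

    def test_missing_background_stroke_raises(self, default_scene):
        image, truth = default_scene
        sc = generate_scribbles(truth, quality="missing_background")
        with pytest.raises(SegmentationError, match="background"):
            segment_foot(image, sc)

    def test_ulcer_mask_recovers_ground_truth(self, default_scene, default_segmentation):
        _, truth = default_scene
        assert iou(default_segmentation.ulcer_mask, truth.ulcer_mask) >= 0.95

    def test_ulcer_never_leaks_outside_foot(self, default_segmentation):
        assert not (
            default_segmentation.ulcer_mask & ~default_segmentation.foot_mask
        ).any()

    def test_leg_distractor_excluded_with_good_scribbles(self):
        image, truth = generate_scene(
            SceneParams(seed=5, distractors=frozenset({"leg_skin"}))
        )
        sc = generate_scribbles(truth, quality="good")
        result = segment_foot(image, sc)
        leg = truth.distractor_masks["leg_skin"]
        assert (result.foot_mask & leg).sum() <= 0.05 * leg.sum()

    def test_stray_tap_on_plain_skin_finds_no_wound(self):
        image, truth = generate_scene(SceneParams(seed=2, ulcer_fraction_target=0.0))
        assert not truth.ulcer_mask.any()
        h, w = truth.foot_mask.shape
        # manual scribbles: good loop + foot strokes, plus a stray tap
        rs, cs = np.nonzero(truth.foot_mask)
        tap = (int(rs.mean()) - 10, int(cs.mean()))
        # build directly: background loop + foot stroke + stray ulcer tap
        from footcheck.synthetic import _contour_loop

        loop = _contour_loop(truth.foot_mask, margin=5)
        strokes = (
            Stroke("background", tuple(loop), 2),
            Stroke("foot", ((int(rs.mean()) + 14, tap[1] - 8), (int(rs.mean()) + 14, tap[1] + 8)), 2),
            Stroke("ulcer", (tap,), 0),
        )
        scribbles = ScribbleSet(strokes, h, w)
        foot = segment_foot(image, scribbles)
        result = segment_ulcer(image, foot.foot_mask, scribbles)
        check = measure(result, dt.datetime(2023, 1, 2))
        assert result.flags.ulcer_empty or check.ulcer_fraction <= 0.005

    def test_edge_crossing_scribbles_are_flagged(self, default_scene):
        image, truth = default_scene
        sc = generate_scribbles(truth, quality="edge_crossing")
        foot = segment_foot(image, sc)
        issues = validate_scribbles(sc, stage="ulcer", foot_mask=truth.ulcer_mask)
        result = segment_ulcer(image, foot.foot_mask, sc)
        assert result.flags.ulcer_touches_foot_edge or any(
            i.kind == "crosses_edge" for i in issues
        )

    def test_ulcer_markers_outside_foot_raise(self, default_scene):
        image, truth = default_scene
        h, w = truth.foot_mask.shape
        sc = ScribbleSet(
            (
                Stroke("foot", ((h // 2, w // 2),), 2),
                Stroke("ulcer", ((1, 1),), 0),  # in the background corner
            ),
            h,
            w,
        )
        with pytest.raises(SegmentationError, match="outside"):
            segment_ulcer(image, truth.foot_mask, sc)


class TestQualityFlags:
    def test_well_formed_interior_foot(self):
        mask = np.zeros((100, 100), bool)
        mask[20:80, 25:75] = True  # 30% of the image, strictly interior
        flags = assess_quality(mask, np.zeros_like(mask), (100, 100))
        assert not flags.foot_touches_border
        assert not flags.foot_area_implausible
        assert not flags.ulcer_touches_foot_edge

    def test_full_frame_mask_is_degenerate(self):
        mask = np.ones((50, 50), bool)
        flags = assess_quality(mask, np.zeros_like(mask), (50, 50))
        assert flags.foot_touches_border
        assert flags.foot_area_implausible

    def test_ulcer_tangent_to_foot_boundary_flagged(self):
        foot = np.zeros((60, 60), bool)
        foot[10:50, 10:50] = True
        ulcer = np.zeros_like(foot)
        ulcer[20:30, 10:20] = True  # shares the foot's left edge
        flags = assess_quality(foot, ulcer, (60, 60))
        assert flags.ulcer_touches_foot_edge

    def test_interior_ulcer_not_flagged(self):
        foot = np.zeros((60, 60), bool)
        foot[10:50, 10:50] = True
        ulcer = np.zeros_like(foot)
        ulcer[25:32, 25:32] = True
        flags = assess_quality(foot, ulcer, (60, 60))
        assert not flags.ulcer_touches_foot_edge
        assert not flags.ulcer_empty
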