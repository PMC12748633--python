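"""Image pipeline stages, each against a simple independent oracle."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from phasedig import image as im
from phasedig import synth
from phasedig.exceptions import EditError, GeometryError, NoRegionsError, NotEnclosedError
from phasedig.image import EditPrimitive, Quadrilateral
from phasedig.sampler import Axis, AxisCalibration

from conftest import random_line_mask


def region_count(mask):
    """Independent area-count oracle: 4-connected label of white pixels."""
    return ndimage.label(np.asarray(mask) == 0, structure=im.FOUR_CONNECTED)[1]


def flood_components(mask):
    """Independent 8-connected component enumeration by explicit flood fill."""
    mask = np.asarray(mask)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack, pixels = [(r, c)], []
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    pixels.append((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                                seen[nr, nc] = True
                                stack.append((nr, nc))
                comps.append(pixels)
    return comps


# ---------------------------------------------------------------------------
# binarize
# ---------------------------------------------------------------------------


class TestBinarize:
    def test_extremes(self):
        assert not im.binarize(np.full((5, 5), 255, np.uint8), 0.5).any()
        assert im.binarize(np.zeros((5, 5), np.uint8), 0.5).all()

    def test_gray_checkerboard_below_threshold(self):
        # 40 % darkness everywhere on the dark squares: all below 0.5
        img = np.full((8, 8), 255, np.uint8)
        img[::2, ::2] = int(round(255 * 0.6))  # darkness 0.4
        mask = im.binarize(img, 0.5)
        expected = (1.0 - img / 255.0) >= 0.5
        assert np.array_equal(mask.astype(bool), expected)
        assert not mask.any()

    def test_non_2d_is_error(self):
        with pytest.raises(ValueError):
            im.binarize(np.zeros((4, 4, 3), np.uint8))


# ---------------------------------------------------------------------------
# frame detection / rectification
# ---------------------------------------------------------------------------


class TestPlotFrame:
    def test_single_rectangle(self):
        mask = np.zeros((40, 60), np.uint8)
        mask[5:30, 10:50] = 1
        mask[6:29, 11:49] = 0
        quad = im.find_plot_frame(mask)
        assert set(map(tuple, quad.corners)) == {(5, 10), (5, 49), (29, 49), (29, 10)}

    def test_prefers_larger_box_over_legend(self):
        mask = np.zeros((60, 80), np.uint8)
        mask[5:50, 5:70] = 1
        mask[6:49, 6:69] = 0
        mask[10:20, 30:45] = 1  # legend box inside
        mask[11:19, 31:44] = 0
        # oracle: enclosed interior area of each flood-filled component
        comps = flood_components(mask)
        areas = []
        for pixels in comps:
            sub = np.zeros(mask.shape, bool)
            for p in pixels:
                sub[p] = True
            areas.append(int(ndimage.binary_fill_holes(sub).sum() - sub.sum()))
        assert max(areas) == (49 - 6) * (69 - 6)
        quad = im.find_plot_frame(mask)
        assert set(map(tuple, quad.corners)) == {(5, 5), (5, 69), (49, 69), (49, 5)}

    def test_open_frame_is_error(self):
        mask = np.zeros((30, 30), np.uint8)
        mask[5, 5:25] = 1
        mask[5:25, 5] = 1
        mask[5:25, 24] = 1  # three sides only
        with pytest.raises(NotEnclosedError):
            im.find_plot_frame(mask)


class TestRectify:
    def test_identity_on_aligned_quad(self):
        rng = np.random.default_rng(0)
        mask = (rng.random((30, 40)) < 0.3).astype(np.uint8)
        quad = Quadrilateral(((0, 0), (0, 39), (29, 39), (29, 0)))
        out = im.rectify(mask, quad, 30, 40)
        assert np.array_equal(out, mask)

    def test_sheared_frame_corners_land_on_output_corners(self):
        spec = synth.half_plane_spec(height=201, width=201, shear_deg=5.0)
        image, truth = synth.generate(spec)
        mask = im.binarize(image)
        quad = im.find_plot_frame(mask)
        # detected corners within 1 px of the analytically sheared corners
        found = np.sort(np.asarray(quad.corners), axis=0)
        expected = np.sort(np.asarray(truth.frame_quad), axis=0)
        assert np.abs(found - expected).max() <= 1.0 + 1e-9
        out = im.rectify(mask, quad, 201, 201)
        # after rectification the frame edges are axis-aligned again
        assert out[:, 100].sum() > 150  # the split line is a straight column

    def test_collinear_corners_are_error(self):
        with pytest.raises(GeometryError):
            Quadrilateral(((0, 0), (0, 10), (0, 20), (0, 30)))


# ---------------------------------------------------------------------------
# keep_largest
# ---------------------------------------------------------------------------


class TestKeepLargest:
    def test_drops_smallest_of_three(self):
        mask = np.zeros((40, 40), np.uint8)
        mask[2:12, 2:12] = 1       # 100 px
        mask[20:30, 20:24] = 1     # 40 px
        mask[35, 1:4] = 1          # 3 px
        out = im.keep_largest(mask, 2)
        comps = flood_components(out)
        assert sorted(len(p) for p in comps) == [40, 100]

    def test_oracle_agreement_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            mask = random_line_mask(rng)
            n = int(rng.integers(1, 4))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = im.keep_largest(mask, n)
            comps = flood_components(mask)
            ranked = sorted(
                comps, key=lambda p: (-len(p), min(r * mask.shape[1] + c for r, c in p))
            )
            keep = set(p for comp in ranked[: min(n, len(ranked))] for p in comp)
            expect = np.zeros_like(mask)
            for r, c in keep:
                expect[r, c] = 1
            assert np.array_equal(out, expect)

    def test_n_too_large_warns_and_returns_unchanged(self):
        mask = np.zeros((10, 10), np.uint8)
        mask[2, 2:5] = 1
        with pytest.warns(UserWarning):
            out = im.keep_largest(mask, 5)
        assert np.array_equal(out, mask)

    def test_empty_mask(self):
        mask = np.zeros((5, 5), np.uint8)
        assert not im.keep_largest(mask, 3).any()

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            mask = random_line_mask(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = im.keep_largest(mask, 2)
            assert not np.any(out & ~mask)


# ---------------------------------------------------------------------------
# edit primitives
# ---------------------------------------------------------------------------


def _cal(h=101, w=101):
    return AxisCalibration(
        temperature=Axis(pixel_min=h - 1, pixel_max=0, data_min=0, data_max=100),
        composition=Axis(pixel_min=0, pixel_max=w - 1, data_min=0, data_max=100),
    )


class TestApplyEdits:
    def test_isotherm_draws_full_width_row(self):
        mask = np.zeros((101, 101), np.uint8)
        out = im.apply_edits(
            mask, [EditPrimitive(kind="isotherm", temperature=25.0)], _cal()
        )
        row = 100 - 25
        assert out[row, :].all()
        assert out.sum() == 101

    def test_extend_horizontal_reaches_frame(self):
        mask = im.add_frame(np.zeros((60, 60), np.uint8))
        mask[30, 1:30] = 1
        out = im.apply_edits(mask, [EditPrimitive(kind="extend", start=(30, 29))])
        assert out[30, 1:59].all()

    def test_extend_45_degrees_hits_analytic_intercept(self):
        mask = im.add_frame(np.zeros((80, 80), np.uint8))
        for i in range(10, 40):
            mask[i, i] = 1
        out = im.apply_edits(mask, [EditPrimitive(kind="extend", start=(39, 39))])
        # the 45-degree line through (39, 39) intercepts the frame at (79, 79);
        # the drawn continuation must end within 1 px of (78, 78)
        new = np.argwhere(out.astype(bool) & ~mask.astype(bool))
        tip = new[np.argmax(new.sum(axis=1))]
        assert abs(tip[0] - 78) <= 1 and abs(tip[1] - 78) <= 1
        # and the continuation is the diagonal itself
        assert all(abs(r - c) <= 1 for r, c in new)

    def test_extend_off_line_is_error(self):
        mask = im.add_frame(np.zeros((30, 30), np.uint8))
        with pytest.raises(EditError):
            im.apply_edits(mask, [EditPrimitive(kind="extend", start=(15, 15))])

    def test_erase_segment(self):
        mask = np.ones((20, 20), np.uint8)
        out = im.apply_edits(
            mask, [EditPrimitive(kind="segment", start=(5, 0), end=(5, 19), value=0)]
        )
        assert not out[5, :].any()


# ---------------------------------------------------------------------------
# thinning
# ---------------------------------------------------------------------------


class TestThin:
    def test_thick_line_becomes_one_pixel(self):
        mask = np.zeros((30, 50), np.uint8)
        mask[14:17, :] = 1  # 3 px thick, spans full width: separates 2 areas
        assert region_count(mask) == 2
        out = im.thin(mask)
        assert region_count(out) == 2
        # one pixel per interior column; the two border columns belong to
        # the (frozen) image border, where the frame lives in real diagrams
        assert np.array_equal(out[:, 1:-1].sum(axis=0), np.ones(48))

    def test_diamond_ring_is_stable(self):
        # diamond ring |r-10| + |c-10| == 6: every pixel touches both the
        # inside and the outside area through its 4-neighbors
        mask = np.zeros((21, 21), np.uint8)
        for r in range(21):
            for c in range(21):
                if abs(r - 10) + abs(c - 10) == 6:
                    mask[r, c] = 1
        out = im.thin(mask)
        assert np.array_equal(out, mask)

    def test_solid_disk_separates_nothing(self):
        mask = np.zeros((30, 30), np.uint8)
        rr, cc = np.indices(mask.shape)
        mask[(rr - 15) ** 2 + (cc - 15) ** 2 <= 64] = 1
        assert region_count(mask) == 1
        out = im.thin(mask)
        assert region_count(out) == 1
        # whatever remains separates nothing and is at most a sliver
        assert out.sum() <= 2

    def test_idempotent_and_area_preserving_on_random_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            mask = random_line_mask(rng)
            once = im.thin(mask)
            assert region_count(once) == region_count(mask)
            assert np.array_equal(im.thin(once), once)
            assert not np.any(once & ~mask)  # thinning only removes ink


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------


class TestLabelRegions:
    def test_blank_mask_is_one_region(self):
        lab = im.label_regions(np.zeros((10, 10), np.uint8))
        assert lab.n == 1
        assert (lab.labels == 1).all()

    def test_vertical_split_gives_two(self):
        mask = np.zeros((20, 20), np.uint8)
        mask[:, 10] = 1
        lab = im.label_regions(mask)
        assert lab.n == 2

    def test_all_ink_is_error(self):
        with pytest.raises(NoRegionsError):
            im.label_regions(np.ones((5, 5), np.uint8))

    def test_labels_are_contiguous(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            mask = random_line_mask(rng)
            lab = im.label_regions(mask)
            present = set(np.unique(lab.labels).tolist())
            assert present <= set(range(0, lab.n + 1))
            assert set(range(1, lab.n + 1)) <= present

    def test_five_region_synthetic_matches_generator(self):
        spec = synth.random_spec(seed=4, n_regions=5, height=201, width=201,
                                 line_width=1)
        image, truth = synth.generate(spec)
        lab = im.label_regions(im.binarize(image))
        assert lab.n == 5
        # areas match polygon areas within a boundary-pixel tolerance
        px_area = 0.5 * 0.5  # 2 px per data unit
        for poly, state in zip(truth.polygons, truth.states):
            # find the raster region whose deep interior lies in this polygon
            found = synth.region_state_map(lab, truth.calibration, truth)
            label = [k for k, v in found.items() if v == state]
            assert len(label) == 1
            raster_area = (lab.labels == label[0]).sum() * px_area
            boundary_slack = 1.2 * poly.length  # ~1 px wide strip around it
            assert abs(raster_area - poly.area) <= boundary_slack
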