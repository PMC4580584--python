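import numpy as np
import pytest

from rootanat import (
    Params,
    SyntheticSpec,
    detect_cells,
    dilate_mask,
    distance_map,
    generate_root,
    initial_root_boundary,
    remove_lateral_roots,
)
from rootanat.detection import (
    RootModel,
    SegmentationError,
    build_root_model,
    recover_missed_cells,
)
from rootanat.segmentation import local_threshold
from rootanat.synthetic import detection_rate, match_cells, mean_area_error


def square_ring(canvas, top, left, side):
    """1-px-thick square ring with the given outer side length."""
    canvas[top, left:left + side] = True
    canvas[top + side - 1, left:left + side] = True
    canvas[top:top + side, left] = True
    canvas[top:top + side, left + side - 1] = True
    return canvas


class TestDilateMask:
    def test_empty_and_full_masks_are_fixed_points(self):
        empty = np.zeros((10, 10), bool)
        full = np.ones((10, 10), bool)
        assert not dilate_mask(empty).any()
        assert dilate_mask(full).all()

    def test_single_pixel_grows_into_anchored_2x2_block(self):
        mask = np.zeros((8, 8), bool)
        mask[3, 4] = True
        out = dilate_mask(mask)
        expected = {(3, 4), (3, 5), (4, 4), (4, 5)}
        assert set(zip(*np.nonzero(out))) == expected

    def test_output_is_superset_of_input(self):
        rng = np.random.default_rng(0)
        mask = rng.uniform(size=(30, 30)) > 0.7
        assert (dilate_mask(mask) | mask).sum() == dilate_mask(mask).sum()


class TestDetectCells:
    def test_empty_mask_yields_no_cells(self):
        assert detect_cells(np.zeros((12, 12), bool)) == []

    def test_square_ring_encloses_one_cell_of_known_area(self):
        mask = square_ring(np.zeros((14, 14), bool), 2, 2, 10)
        cells = detect_cells(mask)
        assert len(cells) == 1
        assert cells[0].area == 64  # 8 x 8 interior
        assert cells[0].centroid == pytest.approx((6.5, 6.5))

    def test_nested_rings_give_inner_square_plus_annulus(self):
        mask = square_ring(np.zeros((22, 22), bool), 1, 1, 20)
        mask = square_ring(mask, 7, 7, 8)
        cells = detect_cells(mask)
        assert len(cells) == 2
        areas = sorted(c.area for c in cells)
        assert areas[0] == 36  # inner 6 x 6
        assert areas[1] == 18 * 18 - 8 * 8  # annulus between the rings

    def test_interiors_are_pairwise_disjoint(self, wheat_case):
        seen = set()
        for cell in wheat_case["model"].cells:
            px = set(zip(*cell.pixels))
            assert not (seen & px)
            seen |= px


class TestRemoveLateralRoots:
    @staticmethod
    def _cells_with_means(means):
        cells = detect_cells(_three_rings())
        assert len(cells) == len(means)
        for cell, m in zip(sorted(cells, key=lambda c: c.centroid[1]), means):
            cell.mean_intensity = m
        return cells

    def test_dark_region_below_one_third_of_mean_removed(self):
        cells = self._cells_with_means([0.6, 0.6, 0.1])
        kept = remove_lateral_roots(cells, np.zeros((1, 1)))
        assert sorted(c.mean_intensity for c in kept) == [0.6, 0.6]

    def test_equal_intensities_keep_everything(self):
        cells = self._cells_with_means([0.4, 0.4, 0.4])
        assert len(remove_lateral_roots(cells, np.zeros((1, 1)))) == 3

    def test_single_cell_never_removed(self):
        mask = square_ring(np.zeros((14, 14), bool), 2, 2, 10)
        cells = detect_cells(mask)
        cells[0].mean_intensity = 0.01
        assert len(remove_lateral_roots(cells, np.zeros((1, 1)))) == 1


def _three_rings():
    mask = np.zeros((16, 40), bool)
    for k in range(3):
        square_ring(mask, 2, 2 + 12 * k, 10)
    return mask


class TestDistanceMap:
    def test_all_foreground_gives_zeros(self):
        assert distance_map(np.ones((9, 9), bool)).max() == 0.0

    def test_single_foreground_pixel_euclidean_values(self):
        mask = np.zeros((20, 20), bool)
        mask[5, 5] = True
        d = distance_map(mask)
        assert d[5, 5] == 0.0
        assert d[8, 9] == pytest.approx(5.0)  # offset (3, 4)

    def test_ring_interior_peak_at_centre(self):
        mask = square_ring(np.zeros((23, 23), bool), 1, 1, 21)
        d = distance_map(mask)
        assert d[11, 11] == pytest.approx(10.0)  # centre-to-wall half-width

    def test_all_background_rejected(self):
        with pytest.raises(ValueError):
            distance_map(np.zeros((5, 5), bool))


class TestInitialRootBoundary:
    def test_circular_ring_boundary_area_close_to_disc(self):
        yy, xx = np.mgrid[0:101, 0:101]
        r = np.hypot(yy - 50, xx - 50)
        mask = (r >= 40) & (r < 42)
        cells = detect_cells(mask)
        assert len(cells) == 1
        _, region = initial_root_boundary(cells, mask)
        assert region.sum() == pytest.approx(np.pi * 42**2, rel=0.05)

    def test_every_centroid_inside_region_and_area_dominates(self, wheat_case):
        model = wheat_case["model"]
        region = model.gamma_final_mask
        for cell in model.cells:
            assert region[int(round(cell.centroid[0])), int(round(cell.centroid[1]))]
        assert region.sum() >= sum(c.area for c in model.cells)

    def test_no_cells_is_an_error(self):
        with pytest.raises(SegmentationError):
            initial_root_boundary([], np.zeros((5, 5), bool))


class TestSyntheticDetection:
    def test_intact_root_cells_recovered_with_small_area_bias(self, wheat_case):
        model, truth = wheat_case["model"], wheat_case["truth"]
        assert detection_rate(model.cells, truth) >= 0.95
        assert mean_area_error(model.cells, truth) <= 0.10

    def test_intact_root_recovery_pass_is_a_no_op(self, wheat_params):
        image, _ = generate_root(SyntheticSpec.wheat(seed=5))
        model = _first_pass_model(image, wheat_params)
        n1 = len(model.cells)
        recover_missed_cells(image, wheat_params, model)
        assert len(model.cells) == n1
        np.testing.assert_array_equal(model.gamma_final_mask, model.gamma_ini_mask)

    def test_faint_walled_cell_is_recovered(self, wheat_params):
        image, truth = generate_root(SyntheticSpec.wheat(seed=3, break_probability=0.05))
        model = _first_pass_model(image, wheat_params)
        n1 = len(model.cells)
        recover_missed_cells(image, wheat_params, model)
        assert len(model.cells) > n1  # broken boundary cells came back
        assert detection_rate(model.cells, truth) == 1.0
        # enlarged boundary encloses the recovered cells
        for cell in model.cells:
            assert model.gamma_final_mask[cell.pixels].all()

    def test_recovery_never_removes_first_pass_cells(self, wheat_params):
        image, _ = generate_root(SyntheticSpec.wheat(seed=3, break_probability=0.05))
        model = _first_pass_model(image, wheat_params)
        first_ids = {c.id for c in model.cells}
        recover_missed_cells(image, wheat_params, model)
        assert first_ids <= {c.id for c in model.cells}

    def test_lateral_root_blob_is_not_reported_as_a_cell(self, wheat_params):
        image, truth = generate_root(SyntheticSpec.wheat(seed=4, lateral_root=True))
        model = build_root_model(image, wheat_params)
        matches = match_cells(model.cells, truth)
        matched_det = set(matches.values())
        dark = [c for c in model.cells if c.id not in matched_det and c.mean_intensity < 0.2]
        assert not dark  # the dark blob interior was filtered out


def _first_pass_model(image, params):
    mask = dilate_mask(local_threshold(image, params.T, params.w, params.polarity))
    cells = remove_lateral_roots(detect_cells(mask, image), image)
    gamma, region = initial_root_boundary(cells, mask)
    return RootModel(cells=cells, gamma_ini=gamma, gamma_final=gamma,
                     gamma_ini_mask=region, gamma_final_mask=region, mask=mask)
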