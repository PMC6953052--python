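import math

import numpy as np
import pytest

from hcscreen.image_analysis import (
    DetectionParams,
    assign_vesicles_to_cells,
    detect_subunit_c_deposits,
    detect_vesicles,
    distance_to_nuclear_border,
    flat_field_correct,
    infer_cell_regions,
    measure_cells,
    nucleus_boundary_pixels,
    segment_nuclei,
    vesicle_centroids,
)
from hcscreen.synthetic import SyntheticSpec, generate_field


def disc(shape, cy, cx, r, value=1.0, base=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, base, float)
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] += value
    return img


def gaussian_spot(img, y, x, amp, sigma=1.5):
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    img += amp * np.exp(-(((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)))
    return img


def brute_force_border_distance(centroid, nuclei):
    """Independent oracle: exhaustive loop over every nuclear boundary pixel."""
    cy, cx = centroid
    iy, ix = int(round(cy)), int(round(cx))
    if nuclei[iy, ix] > 0:
        return 0.0
    from scipy import ndimage as ndi

    mask = nuclei > 0
    interior = ndi.binary_erosion(mask, ndi.generate_binary_structure(2, 1),
                                  border_value=0)
    best = None
    for (by, bx) in np.argwhere(mask & ~interior):
        d2 = (by - cy) ** 2 + (bx - cx) ** 2
        if best is None or d2 < best:
            best = d2
    return float(np.sqrt(best))


class TestFlatField:
    def test_uniform_image_unchanged_up_to_rescaling(self):
        img = np.full((64, 64), 500.0)
        out = flat_field_correct(img)
        np.testing.assert_allclose(out, img, rtol=1e-9)

    def test_known_ramp_recovered_within_one_percent(self):
        rng = np.random.default_rng(0)
        true = 1000.0 + 200.0 * rng.random((128, 128))
        ramp = np.outer(np.linspace(0.5, 1.5, 128), np.ones(128))
        observed = true * ramp
        recovered = flat_field_correct(observed, model=ramp)
        np.testing.assert_allclose(
            recovered / recovered.mean(), true / true.mean(), rtol=0.01
        )

    def test_all_zero_image_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = flat_field_correct(np.zeros((32, 32)))
        assert not out.any()


class TestSegmentNuclei:
    def test_planted_nuclei_recovered(self):
        spec = SyntheticSpec(seed=21, field_shape=(512, 512), cells_per_field=20.0,
                             nucleus_diameter_px=(38.0, 42.0))
        img, truth = generate_field(spec, "A01", 0, n_cells=20)
        labels = segment_nuclei(img.nuclear.astype(float))
        assert labels.max() == 20

    def test_object_below_diameter_range_rejected(self):
        img = disc((128, 128), 64, 64, 10, value=20000.0, base=300.0)  # diameter 20
        labels = segment_nuclei(img)
        assert labels.max() == 0

    def test_bright_object_in_range_accepted(self):
        img = disc((256, 256), 128, 128, 25, value=25000.0, base=300.0)  # diameter 50
        labels = segment_nuclei(img)
        assert labels.max() == 1

    def test_dim_object_rejected(self):
        img = disc((256, 256), 128, 128, 25, value=300.0, base=300.0)
        labels = segment_nuclei(img, min_above_background=500.0)
        assert labels.max() == 0

    def test_empty_image_gives_empty_label_map(self):
        labels = segment_nuclei(np.full((64, 64), 300.0))
        assert labels.shape == (64, 64) and labels.max() == 0

    def test_touching_nuclei_split(self):
        img = np.full((160, 160), 300.0)
        img += disc((160, 160), 80, 60, 18, value=20000.0)
        img += disc((160, 160), 80, 99, 18, value=20000.0)  # 1 px gap
        labels = segment_nuclei(img)
        assert labels.max() == 2


class TestDetectVesicles:
    def test_empty_field_has_no_vesicles(self):
        assert detect_vesicles(np.full((128, 128), 400.0)).max() == 0

    def test_planted_spots_recovered_with_subpixel_centroids(self):
        rng = np.random.default_rng(3)
        img = np.full((512, 512), 400.0)
        pts = []
        while len(pts) < 50:
            y, x = rng.uniform(20, 492, 2)
            if all((y - p[0]) ** 2 + (x - p[1]) ** 2 > 20**2 for p in pts):
                pts.append((y, x))
        for y, x in pts:
            gaussian_spot(img, y, x, 12000.0)
        labels = detect_vesicles(img)
        assert labels.max() == 50
        centroids = vesicle_centroids(labels)
        from scipy.spatial import cKDTree

        dd, _ = cKDTree(np.array(pts)).query(centroids)
        assert dd.max() < 1.0

    def test_detection_invariant_to_constant_offset(self):
        img = np.full((256, 256), 400.0)
        for y, x in [(50, 60), (100, 200), (180, 40)]:
            gaussian_spot(img, y, x, 12000.0)
        base = detect_vesicles(img)
        shifted = detect_vesicles(img + 5000.0)
        np.testing.assert_array_equal(base, shifted)

    def test_touching_puncta_split_by_peaks(self):
        img = np.full((64, 64), 400.0)
        gaussian_spot(img, 32, 28, 12000.0)
        gaussian_spot(img, 32, 34, 12000.0)
        assert detect_vesicles(img).max() == 2


class TestCellRegions:
    def test_single_cell_region_covers_cytoplasm_disc(self):
        nuclear = disc((256, 256), 128, 128, 18, value=20000.0, base=300.0)
        red = disc((256, 256), 128, 128, 45, value=4000.0, base=5000.0)
        nuclei = segment_nuclei(nuclear)
        assert nuclei.max() == 1
        regions = infer_cell_regions(red, nuclei)
        assert regions.max() == 1
        truth_mask = disc((256, 256), 128, 128, 45) > 0
        overlap = (regions > 0) & truth_mask
        assert overlap.sum() / truth_mask.sum() >= 0.9

    def test_two_separated_cells_give_disjoint_regions(self):
        nuclear = np.full((256, 256), 300.0)
        nuclear += disc((256, 256), 64, 64, 16, value=20000.0)
        nuclear += disc((256, 256), 192, 192, 16, value=20000.0)
        red = np.full((256, 256), 5000.0)
        red += disc((256, 256), 64, 64, 40, value=4000.0)
        red += disc((256, 256), 192, 192, 40, value=4000.0)
        nuclei = segment_nuclei(nuclear)
        regions = infer_cell_regions(red, nuclei)
        assert set(np.unique(regions)) == {0, 1, 2}

    def test_no_nuclei_gives_empty_map(self):
        regions = infer_cell_regions(np.full((64, 64), 5000.0), np.zeros((64, 64), int))
        assert regions.max() == 0


class TestAssignment:
    def _maps(self):
        cells = np.zeros((64, 64), np.int32)
        cells[5:30, 5:30] = 2
        cells[35:60, 35:60] = 3
        vesicles = np.zeros((64, 64), np.int32)
        return cells, vesicles

    def test_centroid_inside_cell(self):
        cells, vesicles = self._maps()
        vesicles[40:42, 40:42] = 1
        assign, dropped = assign_vesicles_to_cells(vesicles, cells)
        assert assign == {3: [1]} and dropped == 0

    def test_centroid_on_background_within_gap_assigned_to_nearest(self):
        cells, vesicles = self._maps()
        vesicles[31:33, 10:12] = 1  # 2 px below region 2
        assign, dropped = assign_vesicles_to_cells(vesicles, cells, max_gap_px=5)
        assert assign == {2: [1]} and dropped == 0

    def test_far_vesicle_dropped_and_counted(self):
        cells = np.zeros((128, 128), np.int32)
        cells[0:10, 0:10] = 1
        vesicles = np.zeros((128, 128), np.int32)
        vesicles[100:102, 100:102] = 1
        assign, dropped = assign_vesicles_to_cells(vesicles, cells, max_gap_px=5)
        assert assign == {} and dropped == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_vesicles_to_cells(np.zeros((4, 4), int), np.zeros((5, 5), int))


class TestMeasureCells:
    def _field(self):
        """One cell: nucleus disc radius 5 at (32, 32), cell covers all."""
        nuclei = np.zeros((64, 64), np.int32)
        yy, xx = np.mgrid[0:64, 0:64]
        nuclei[(yy - 32) ** 2 + (xx - 32) ** 2 <= 25] = 1
        cells = np.ones((64, 64), np.int32)
        return cells, nuclei

    def test_distance_from_disc_border(self):
        """Nucleus = disc of radius 5, vesicle centroid 8 px right of center:
        distance is 3 um at 1 um/px (nearest boundary pixel at (32, 37))."""
        cells, nuclei = self._field()
        red = np.zeros((64, 64), np.int32)
        red[32, 40] = 1
        green = np.zeros_like(red)
        records = measure_cells(cells, nuclei, green, red)
        assert len(records) == 1
        assert records[0].red_distances == [pytest.approx(3.0)]

    def test_vesicle_inside_nucleus_scores_zero(self):
        cells, nuclei = self._field()
        red = np.zeros((64, 64), np.int32)
        red[32, 33] = 1
        records = measure_cells(cells, nuclei, np.zeros_like(red), red)
        assert records[0].red_distances == [0.0]

    def test_five_green_vesicles_is_positive(self):
        cells, nuclei = self._field()
        green = np.zeros((64, 64), np.int32)
        for i, (y, x) in enumerate([(10, 10), (10, 20), (20, 10), (50, 50), (50, 10)], 1):
            green[y, x] = i
        records = measure_cells(cells, nuclei, green, np.zeros_like(green))
        assert records[0].green_count == 5
        assert records[0].is_positive

    def test_four_green_vesicles_is_negative(self):
        cells, nuclei = self._field()
        green = np.zeros((64, 64), np.int32)
        for i, (y, x) in enumerate([(10, 10), (10, 20), (20, 10), (50, 50)], 1):
            green[y, x] = i
        records = measure_cells(cells, nuclei, green, np.zeros_like(green))
        assert not records[0].is_positive

    def test_cell_without_nucleus_excluded(self):
        cells, nuclei = self._field()
        cells[0:5, 0:5] = 2  # extra region with no nucleus
        records = measure_cells(cells, nuclei, np.zeros_like(cells), np.zeros_like(cells))
        assert [r.cell_id for r in records] == [1]

    def test_um_per_pixel_scales_distances(self):
        cells, nuclei = self._field()
        red = np.zeros((64, 64), np.int32)
        red[32, 40] = 1
        records = measure_cells(cells, nuclei, np.zeros_like(red), red, um_per_pixel=0.5)
        assert records[0].red_distances == [pytest.approx(1.5)]

    def test_relabeling_invariance(self):
        """Permuting label ids changes no readout."""
        spec = SyntheticSpec(seed=13, field_shape=(256, 256), cells_per_field=6.0)
        img, _ = generate_field(spec, "A01", 0)
        nuclei = segment_nuclei(img.nuclear.astype(float))
        cells = infer_cell_regions(img.red.astype(float), nuclei)
        green = detect_vesicles(img.green.astype(float))
        red = detect_vesicles(img.red.astype(float))
        base = measure_cells(cells, nuclei, green, red)

        rng = np.random.default_rng(0)
        perm = np.concatenate([[0], rng.permutation(np.arange(1, green.max() + 1))])
        green_perm = perm[green]
        base_perm = measure_cells(cells, nuclei, green_perm, red)
        assert [r.green_count for r in base] == [r.green_count for r in base_perm]
        assert [sorted(np.round(r.red_distances, 9)) for r in base] == [
            sorted(np.round(r.red_distances, 9)) for r in base_perm
        ]


class TestDistanceOracle:
    def test_pipeline_distance_equals_brute_force_exactly(self):
        """Distance-to-nearest-nuclear-border equals an exhaustive minimum
        over all boundary pixels, exactly."""
        rng = np.random.default_rng(42)
        nuclei = np.zeros((128, 128), np.int32)
        yy, xx = np.mgrid[0:128, 0:128]
        for lab, (cy, cx, r) in enumerate(
            [(30, 30, 9), (90, 40, 12), (60, 100, 7)], start=1
        ):
            nuclei[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = lab
        boundary = nucleus_boundary_pixels(nuclei)
        for _ in range(50):
            pt = tuple(rng.uniform(0, 127, 2))
            fast = distance_to_nuclear_border(pt, nuclei, boundary=boundary)
            assert fast == brute_force_border_distance(pt, nuclei)


class TestRecovery:
    def test_positive_fraction_and_distance_recovered_on_default_fields(self):
        """Pooled over >= 300 cells at baseline conditions, the measured
        %-positive is within 3 points of planted and the pooled mean
        lysosome-to-nucleus distance within 0.25 um of planted."""
        p = DetectionParams()
        spec = SyntheticSpec(seed=17)
        pos_m, pos_p, d_m, d_p = [], [], [], []
        for f in range(6):
            img, truth = generate_field(spec, "A01", f)
            nuclei = segment_nuclei(flat_field_correct(img.nuclear), params=p)
            cells = infer_cell_regions(flat_field_correct(img.red), nuclei, p)
            gv = detect_vesicles(flat_field_correct(img.green), "green", p)
            rv = detect_vesicles(flat_field_correct(img.red), "red", p)
            records = measure_cells(cells, nuclei, gv, rv)
            pos_m += [r.is_positive for r in records]
            pos_p += list(truth.cells.is_positive)
            d_m += [d for r in records for d in r.red_distances]
            d_p += list(truth.red_vesicles.distance_um)
        assert len(pos_m) >= 300
        assert abs(100 * np.mean(pos_m) - 100 * np.mean(pos_p)) < 3.0
        assert abs(np.mean(d_m) - np.mean(d_p)) < 0.25

    def test_green_count_monotone_in_planted_puncta(self):
        """Adding an extra punctum to a cell never decreases its count."""
        spec = SyntheticSpec(seed=19, field_shape=(256, 256), cells_per_field=5.0)
        img, truth = generate_field(spec, "A01", 0)
        green = img.green.astype(float)
        nuclei = segment_nuclei(img.nuclear.astype(float))
        cells = infer_cell_regions(img.red.astype(float), nuclei)
        before = measure_cells(cells, nuclei, detect_vesicles(green), np.zeros_like(nuclei))
        # drop an extra bright spot next to the first cell's nucleus
        cell = truth.cells.iloc[0]
        green2 = green.copy()
        gaussian_spot(green2, cell.y + cell.radius_px + 6, cell.x, 12000.0)
        after = measure_cells(cells, nuclei, detect_vesicles(green2), np.zeros_like(nuclei))
        counts_before = {r.cell_id: r.green_count for r in before}
        counts_after = {r.cell_id: r.green_count for r in after}
        assert all(counts_after[c] >= counts_before[c] for c in counts_before)
        assert sum(counts_after.values()) == sum(counts_before.values()) + 1


class TestDeposits:
    def _nuclei(self, shape=(256, 256)):
        nuclear = np.full(shape, 300.0)
        for cy, cx in [(50, 50), (50, 200), (200, 50), (200, 200)]:
            nuclear += disc(shape, cy, cx, 17, value=20000.0)
        return segment_nuclei(nuclear)

    def test_wide_bright_deposit_detected(self):
        nuclei = self._nuclei()
        img = disc((256, 256), 128, 128, 10, value=25000.0, base=300.0)  # width 20
        labels, per_cell = detect_subunit_c_deposits(img, nuclei)
        assert labels.max() == 1
        assert per_cell == pytest.approx(0.25)

    def test_narrow_deposit_rejected(self):
        nuclei = self._nuclei()
        img = disc((256, 256), 128, 128, 5, value=25000.0, base=300.0)  # width 10
        labels, per_cell = detect_subunit_c_deposits(img, nuclei)
        assert labels.max() == 0 and per_cell == 0.0

    def test_low_contrast_deposit_rejected(self):
        nuclei = self._nuclei()
        img = disc((256, 256), 128, 128, 10, value=15000.0, base=300.0)
        labels, _ = detect_subunit_c_deposits(img, nuclei)
        assert labels.max() == 0

    def test_deposits_per_cell_ratio(self):
        nuclei = self._nuclei()
        img = np.full((256, 256), 300.0)
        img += disc((256, 256), 100, 128, 10, value=25000.0)
        img += disc((256, 256), 160, 128, 10, value=25000.0)
        _, per_cell = detect_subunit_c_deposits(img, nuclei)
        assert per_cell == pytest.approx(2 / 4)

    def test_zero_nuclei_gives_na(self):
        img = disc((128, 128), 64, 64, 10, value=25000.0, base=300.0)
        _, per_cell = detect_subunit_c_deposits(img, np.zeros((128, 128), np.int32))
        assert per_cell is None
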