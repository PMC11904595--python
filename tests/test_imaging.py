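"""Imaging pipeline: background, segmentation, ratios, rank test."""

import itertools
import math

import numpy as np
import pytest

from golgiredox.imaging import (
    FieldOfView,
    compare_conditions,
    correct_background,
    default_denominator_floor,
    per_cell_ratio_table,
    segment_cells,
    segment_golgi,
)
from golgiredox.synth import ImagingScenario, simulate_fov


class TestBackgroundCorrection:
    def test_uniform_plane_maps_to_zero(self):
        assert np.all(correct_background(np.full((64, 64), 100.0), block=16) == 0)

    def test_zero_plane_stays_zero(self):
        assert np.all(correct_background(np.zeros((64, 64)), block=16) == 0)

    def test_constant_offset_removed_away_from_objects(self, make_disks):
        clean = make_disks((96, 96), [(48, 48)], 10, 500.0)
        corrected = correct_background(clean + 50.0, block=32)
        # compare off a border around the object where smoothing bleeds
        yy, xx = np.mgrid[0:96, 0:96]
        far = (yy - 48) ** 2 + (xx - 48) ** 2 > 40**2
        assert np.allclose(corrected[far], clean[far], atol=1.0)

    def test_block_larger_than_image_falls_back_with_warning(self):
        img = np.full((32, 32), 7.0)
        with pytest.warns(UserWarning, match="global-minimum"):
            out = correct_background(img, block=600)
        assert np.all(out == 0)

    def test_idempotent_on_own_output(self, make_disks):
        img = make_disks((96, 96), [(30, 30), (70, 66)], 8, 400.0, background=25.0)
        once = correct_background(img, block=32)
        twice = correct_background(once, block=32)
        assert np.allclose(once, twice, atol=1e-6)


class TestSegmentCells:
    def test_pure_noise_has_no_objects(self, rng):
        noise = rng.normal(100.0, 3.0, (128, 128))
        labels = segment_cells(np.clip(noise, 0, None))
        assert labels.max() == 0

    def test_two_disjoint_disks_are_two_cells(self, make_disks):
        img = make_disks((128, 128), [(40, 40), (90, 90)], 12, 300.0, 10.0)
        labels = segment_cells(img, min_cell_area=100)
        assert labels.max() == 2

    def test_corner_contact_bridged_only_by_8_connectivity(self):
        # two blocks meeting at a single diagonal corner: one object under
        # 8-connectivity, two under 4-connectivity
        img = np.zeros((128, 128))
        img[20:50, 20:50] = 300.0
        img[50:80, 50:80] = 300.0
        assert segment_cells(img, min_cell_area=50, connectivity=2).max() == 1
        assert segment_cells(img, min_cell_area=50, connectivity=1).max() == 2

    def test_small_objects_removed(self, make_disks):
        img = make_disks((128, 128), [(64, 64)], 3, 300.0, 0.0)
        assert segment_cells(img, min_cell_area=200).max() == 0


class TestSegmentGolgi:
    def _cell_with_blob(self, make_disks):
        body = make_disks((128, 128), [(64, 64)], 25, 60.0, 0.0)
        spot = make_disks((128, 128), [(56, 60)], 4, 400.0, 0.0)
        return np.maximum(body, spot)

    def test_blob_inside_cell_is_mapped(self, make_disks):
        img = self._cell_with_blob(make_disks)
        cells = segment_cells(img, min_cell_area=200)
        seg = segment_golgi(img, cells, spot_scale=6, min_golgi_area=5)
        assert set(seg.golgi_to_cell.values()) == {1}
        assert seg.golgi_labels.max() == 1

    def test_spot_outside_cells_is_excluded(self, make_disks):
        img = self._cell_with_blob(make_disks)
        img = np.maximum(img, make_disks((128, 128), [(15, 110)], 4, 400.0, 0.0))
        cells = segment_cells(img, min_cell_area=200)
        seg = segment_golgi(img, cells, spot_scale=6, min_golgi_area=5)
        # lone bright spot forms its own "cell" only if large enough; with
        # min_cell_area=200 it is not a cell, so its pixels map nowhere
        assert all(
            cells[seg.golgi_labels == g].max() == c
            for g, c in seg.golgi_to_cell.items()
        )
        assert seg.golgi_labels[10:20, 105:115].max() == 0

    def test_cell_without_enhanced_pixels_yields_empty_mapping(self, make_disks):
        # a constant plane has zero top-hat response everywhere, so a cell
        # footprint without spots produces no Golgi group
        cells = (make_disks((128, 128), [(64, 64)], 25, 1.0, 0.0) > 0).astype(int)
        flat = np.full((128, 128), 60.0)
        seg = segment_golgi(flat, cells, spot_scale=6, min_golgi_area=5)
        assert seg.golgi_to_cell == {}
        assert seg.golgi_labels.max() == 0


class TestPerCellRatios:
    def _segmented_field(self, make_disks, num_scale=2.0):
        den = make_disks((128, 128), [(64, 64)], 25, 60.0, 0.0)
        den = np.maximum(den, make_disks((128, 128), [(56, 60)], 4, 400.0, 0.0))
        fov = FieldOfView(channels=(num_scale * den, den))
        cells = segment_cells(den, min_cell_area=200)
        seg = segment_golgi(den, cells, spot_scale=6, min_golgi_area=5)
        return fov, seg

    def test_proportional_channels_give_constant_ratio(self, make_disks):
        fov, seg = self._segmented_field(make_disks, num_scale=2.0)
        records, exclusions = per_cell_ratio_table(fov, seg)
        assert exclusions == []
        assert len(records) == 1
        assert records[0].ratio == pytest.approx(2.0)

    def test_zero_denominator_excludes_all_cells(self, make_disks):
        fov, seg = self._segmented_field(make_disks)
        dead = FieldOfView(channels=(fov.numerator, np.zeros_like(fov.denominator)))
        records, exclusions = per_cell_ratio_table(dead, seg, den_floor=1.0)
        assert records == []
        assert len(exclusions) == len(seg.golgi_to_cell)

    def test_intensity_scale_equivariance(self, make_disks):
        fov, seg = self._segmented_field(make_disks)
        scaled = FieldOfView(
            channels=(fov.numerator * 7.0, fov.denominator * 7.0)
        )
        cells2 = segment_cells(scaled.denominator, min_cell_area=200)
        assert np.array_equal(cells2, seg.cell_labels)
        r1, _ = per_cell_ratio_table(fov, seg)
        r2, _ = per_cell_ratio_table(scaled, seg)
        assert r1[0].ratio == pytest.approx(r2[0].ratio, rel=1e-12)

    def test_simulated_field_ratio_recovery(self):
        scenario = ImagingScenario(
            n_cells=30,
            true_ratio_per_condition={"basal": 1.5},
            dispersion=0.0,
            seed=42,
        )
        fov, _ = simulate_fov(scenario, "basal")
        num = correct_background(fov.numerator, block=64)
        den = correct_background(fov.denominator, block=64)
        cells = segment_cells(den)
        seg = segment_golgi(den, cells)
        records, _ = per_cell_ratio_table(
            FieldOfView(channels=(num, den)), seg
        )
        assert len(records) >= 25
        ratios = np.array([r.ratio for r in records])
        assert np.median(ratios) == pytest.approx(1.5, rel=0.05)


def mannwhitney_exact_oracle(a, b):
    """Brute-force enumeration of all rank assignments (no ties)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum(1 for x in xs for y in ys if x > y))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestCompareConditions:
    def test_full_separation(self):
        u, p = compare_conditions([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 rank assignments

    def test_interleaved_samples_are_not_distinguished(self):
        u, p = compare_conditions([1.0, 3.0, 5.0], [2.0, 4.0, 6.0])
        assert abs(u - 4.5) <= 1.5  # near n1*n2/2
        assert p > 0.5

    def test_identical_pooled_values(self):
        assert compare_conditions([5.0] * 4, [5.0] * 4) == (8.0, 1.0)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 6), (3, 6)])
    def test_agrees_with_enumeration_oracle(self, n1, n2, rng):
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1.0))
            a, b = pooled[:n1], pooled[n1:]
            u_ref, p_ref = mannwhitney_exact_oracle(a, b)
            u, p = compare_conditions(a, b)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(1.0, 0.1, 60)
        b = rng.normal(1.3, 0.1, 60)
        _, p = compare_conditions(a, b)
        assert p < 1e-6

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0, 2.0], [3.0, 4.0, 5.0])
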