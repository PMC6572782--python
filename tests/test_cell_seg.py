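"""Cell segmentation: widefield projection, contrast, watershed, filtering."""

from __future__ import annotations

import numpy as np
import pytest

from smfishquant import cell_seg
from smfishquant.cell_seg import CellMap2D
from smfishquant.nuclei_seg import NucleusMap3D


class TestWidefieldProjection:
    def test_dominant_last_plane(self, rng):
        vol = rng.random((10, 8, 8))
        vol[9] = 10.0
        np.testing.assert_array_equal(
            cell_seg.widefield_projection(vol, n_last=5), vol[9]
        )

    def test_n_last_equals_n_z_is_full_projection(self, rng):
        vol = rng.random((6, 8, 8))
        np.testing.assert_array_equal(
            cell_seg.widefield_projection(vol, n_last=6), vol.max(axis=0)
        )

    def test_matches_bruteforce_over_last_planes(self, rng):
        vol = rng.random((25, 12, 12))
        expected = vol[20:25].max(axis=0)
        np.testing.assert_array_equal(
            cell_seg.widefield_projection(vol, n_last=5), expected
        )

    def test_n_last_out_of_range(self, rng):
        with pytest.raises(ValueError):
            cell_seg.widefield_projection(rng.random((4, 8, 8)), n_last=5)


class TestSubtractBackground:
    def test_constant_image_goes_to_zero(self):
        out = cell_seg.subtract_background(np.full((40, 40), 57.0), disk_radius=5)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_isolated_peak_preserved(self):
        """A single bright pixel loses almost nothing to a wide background filter."""
        img = np.zeros((51, 51))
        img[25, 25] = 1000.0
        out = cell_seg.subtract_background(img, disk_radius=15)
        # disk mean removes only amplitude / n_disk_pixels
        assert out[25, 25] > 995.0

    def test_linear_ramp_removed_away_from_edges(self):
        """A smooth ramp is its own local mean, so the interior residual ~ 0."""
        img = np.tile(np.arange(64, dtype=float), (64, 1))
        out = cell_seg.subtract_background(img, disk_radius=4)
        assert np.abs(out[10:-10, 10:-10]).max() < 1e-6

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            cell_seg.subtract_background(np.zeros((8, 8)), disk_radius=0)


def _two_cell_scene(touching: bool):
    """Two flat-top cells with single-pixel nucleus seeds; returns (contrast, seeds)."""
    img = np.zeros((64, 96))
    yy, xx = np.mgrid[0:64, 0:96]
    cx2 = 58 if touching else 70
    for label, cx in ((1, 30), (2, cx2)):
        r2 = ((xx - cx) ** 2 + (yy - 32) ** 2) / 15.0**2
        profile = np.where(r2 <= 1, 100.0 * (1 - 0.35 * r2**2), 0.0)
        np.maximum(img, profile, out=img)
    seeds = np.zeros((64, 96), dtype=np.int32)
    seeds[32, 30] = 1
    seeds[32, cx2] = 2
    return img, seeds


class TestSegmentCells:
    def test_two_separated_cells(self):
        contrast, seeds = _two_cell_scene(touching=False)
        cells = cell_seg.segment_cells(contrast, seeds)
        assert cells.n_cells == 2
        assert cells.labels[32, 30] == 1 and cells.labels[32, 70] == 2
        # the two footprints are disjoint blobs around their seeds
        assert (cells.labels == 1).sum() > 100 and (cells.labels == 2).sum() > 100

    def test_touching_cells_split_at_ridge(self):
        contrast, seeds = _two_cell_scene(touching=True)
        cells = cell_seg.segment_cells(contrast, seeds)
        assert cells.n_cells == 2
        # boundary between the two labels falls near the midline x ~ 44
        ys, xs = np.nonzero(cells.labels == 1)
        assert xs.max() <= 47
        ys, xs = np.nonzero(cells.labels == 2)
        assert xs.min() >= 41

    def test_single_seed_uniform_contrast(self):
        seeds = np.zeros((32, 32), dtype=np.int32)
        seeds[16, 16] = 1
        cells = cell_seg.segment_cells(np.ones((32, 32)), seeds)
        assert cells.n_cells == 1
        assert (cells.labels == 1).all()

    def test_zero_nuclei_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            cells = cell_seg.segment_cells(np.ones((16, 16)), np.zeros((16, 16), int))
        assert cells.n_cells == 0


class TestFilterCells:
    def _map_with(self, labels):
        return CellMap2D(labels=np.asarray(labels, dtype=np.int32))

    def test_border_cell_removed(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[0:30, 0:30] = 1  # touches border
        labels[35:45, 35:45] = 2  # interior, area 100
        filtered, _ = cell_seg.filter_cells(
            self._map_with(labels), area_bounds=(50, 5000), border_margin=5
        )
        assert list(np.unique(filtered.labels)) == [0, 1]
        assert (filtered.labels[35:45, 35:45] == 1).all()

    def test_small_cell_removed(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[30:33, 30:33] = 1  # area 9
        filtered, _ = cell_seg.filter_cells(
            self._map_with(labels), area_bounds=(50, 5000), border_margin=5
        )
        assert filtered.n_cells == 0

    def test_planted_valid_cells_survive_border_cells_do_not(self):
        """A scene with 10 interior cells and 2 border cells keeps exactly 10."""
        from smfishquant.synthetic import SceneSpec, generate_field
        from smfishquant import pipeline, RunConfig

        spec = SceneSpec(seed=21, n_cells=10, n_border_cells=2)
        stack, truth = generate_field(spec)
        assert truth.cells["valid"].sum() == 10
        result = pipeline.segment_stack(stack, RunConfig())
        assert result.cells.n_cells == 10

    def test_idempotent(self, processed_field):
        _, _, result, _ = processed_field
        again, _ = cell_seg.filter_cells(
            result.cells, area_bounds=result.cells.area_bounds,
            border_margin=result.cells.border_margin
        )
        np.testing.assert_array_equal(again.labels, result.cells.labels)

    def test_nucleus_labels_remapped_in_lockstep(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[0:30, 0:30] = 1  # dropped (border)
        labels[35:45, 35:45] = 2  # kept, becomes 1
        nuc = np.zeros((3, 64, 64), dtype=np.int32)
        nuc[:, 10:15, 10:15] = 1
        nuc[:, 38:42, 38:42] = 2
        nuclei = NucleusMap3D(labels=nuc, per_label_threshold={1: 5.0, 2: 7.0})
        cells, new_nuclei = cell_seg.filter_cells(
            self._map_with(labels), area_bounds=(50, 5000), border_margin=5,
            nuclei=nuclei,
        )
        assert cells.n_cells == 1
        assert set(np.unique(new_nuclei.labels)) == {0, 1}
        assert (new_nuclei.labels[:, 38:42, 38:42] == 1).all()
        assert new_nuclei.per_label_threshold == {1: 7.0}

    def test_cell_nucleus_bijection_after_filtering(self, processed_field):
        _, _, result, _ = processed_field
        cell_ids = set(result.cells.label_ids.tolist())
        nuc_ids = set(result.nuclei.label_ids.tolist())
        assert cell_ids == nuc_ids
        footprint = result.nuclei.footprint_2d()
        for k in cell_ids:
            ys, xs = np.nonzero(footprint == k)
            # the nucleus footprint lies inside its own cell
            assert (result.cells.labels[ys, xs] == k).mean() > 0.9


class TestMeasureCells:
    def test_filled_square(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:20, 5:15] = 1
        (rec,) = cell_seg.measure_cells(CellMap2D(labels=labels))
        assert rec.area == 100
        assert rec.centroid == (9.5, 14.5)  # (x, y)

    def test_filled_disk_axes_nearly_equal(self):
        yy, xx = np.mgrid[0:64, 0:64]
        labels = (((yy - 32) ** 2 + (xx - 32) ** 2) <= 14**2).astype(np.int32)
        (rec,) = cell_seg.measure_cells(CellMap2D(labels=labels))
        assert rec.major_axis == pytest.approx(rec.minor_axis, rel=0.02)

    def test_single_pixel_region(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[3, 5] = 1
        (rec,) = cell_seg.measure_cells(CellMap2D(labels=labels))
        assert rec.area == 1
        assert rec.centroid == (5.0, 3.0)

    def test_additive_offset_invariance_of_segmentation(self, rng):
        """Adding a constant to the widefield image does not change cells."""
        contrast_base, seeds = _two_cell_scene(touching=False)
        raw = contrast_base + 500.0
        c1 = cell_seg.subtract_background(contrast_base, disk_radius=15)
        c2 = cell_seg.subtract_background(raw, disk_radius=15)
        np.testing.assert_allclose(c1, c2, atol=1e-8)
        np.testing.assert_array_equal(
            cell_seg.segment_cells(c1, seeds).labels,
            cell_seg.segment_cells(c2, seeds).labels,
        )
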