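"""Stitching, background correction, colony detection/exclusion/extraction."""

import numpy as np
import pytest

from gastruloid_quant.colony import (FieldImage, correct_background,
                                     detect_colonies, extract_colony,
                                     filter_colonies, stitch_tiles)
from gastruloid_quant.nuclei import segment_colony
from gastruloid_quant.scenes import (IntensityModel, SceneSpec,
                                     generate_multicolony_field)

DENSE = dict(colony_radius=100.0, density=3700.0)


def _field(seed, layout=((150.0, 150.0), (600.0, 150.0), (380.0, 560.0)),
           **spec_kw):
    kw = dict(DENSE)
    kw.update(spec_kw)
    spec = SceneSpec(seed=seed, **kw)
    return spec, *generate_multicolony_field(spec, list(layout))


class TestStitch:
    def test_single_tile_is_identity(self):
        arr = np.random.default_rng(0).random((1, 40, 50)).astype(np.float32)
        out = stitch_tiles([(0, 0, 0, 0, arr)], overlap=0.1)
        assert np.allclose(out.raster, arr)

    def test_zero_overlap_is_concatenation(self):
        r = np.random.default_rng(1).random((1, 20, 20)).astype(np.float32)
        tiles = [(0, 0, 0, 0, r), (0, 1, 0, 20, r + 1),
                 (1, 0, 20, 0, r + 2), (1, 1, 20, 20, r + 3)]
        out = stitch_tiles(tiles, overlap=0.0)
        assert np.allclose(out.raster[:, :20, :20], r)
        assert np.allclose(out.raster[:, 20:, 20:], r + 3)

    def test_tile_reassembly_matches_single_shot(self):
        _, field, _ = _field(2)
        tiles, _ = generate_multicolony_field(
            SceneSpec(seed=2, **DENSE),
            [(150.0, 150.0), (600.0, 150.0), (380.0, 560.0)],
            tile_grid=(2, 2), tile_overlap=0.1)
        out = stitch_tiles(tiles)
        assert out.raster.shape == field.raster.shape
        assert np.abs(out.raster - field.raster).max() < 1e-5

    def test_missing_tile_names_slot(self):
        arr = np.zeros((1, 10, 10), dtype=np.float32)
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            stitch_tiles([(0, 0, 0, 0, arr), (1, 0, 9, 0, arr),
                          (1, 1, 9, 9, arr)], overlap=0.1)

    def test_inconsistent_shapes_rejected(self):
        a = np.zeros((1, 10, 10), dtype=np.float32)
        b = np.zeros((1, 12, 10), dtype=np.float32)
        with pytest.raises(ValueError, match="shapes"):
            stitch_tiles([(0, 0, 0, 0, a), (0, 1, 0, 9, b)], overlap=0.1)


class TestBackground:
    def test_constant_offset_maps_to_zero(self):
        field = FieldImage(np.full((1, 120, 120), 0.3, dtype=np.float32),
                           1.0, ["DAPI"])
        out = correct_background(field, window=40.0)
        assert np.abs(out.raster).max() < 1e-6

    def test_ramp_removed_preserving_nuclear_medians(self):
        """A linear illumination ramp shifts medians < 5% after correction."""
        spec, field, truth = _field(3)
        ramp = np.linspace(0.0, 0.6, field.raster.shape[2])[None, None, :]
        ramped = FieldImage(field.raster + ramp.astype(np.float32), 1.0,
                            list(field.channel_names))
        corr = correct_background(ramped, window=60.0)
        reg = filter_colonies(detect_colonies(corr, 100.0), 100.0)[0]
        col_c = extract_colony(corr, reg, 100.0)
        cells_c, _ = segment_colony(col_c)
        plain = correct_background(field, window=60.0)
        reg0 = filter_colonies(detect_colonies(plain, 100.0), 100.0)[0]
        cells_0, _ = segment_colony(extract_colony(plain, reg0, 100.0))
        m_c = np.median(cells_c["median_DAPI"])
        m_0 = np.median(cells_0["median_DAPI"])
        assert abs(m_c - m_0) / m_0 < 0.05

    def test_idempotent_on_corrected_field(self):
        spec, field, _ = _field(4)
        once = correct_background(field, window=60.0)
        twice = correct_background(once, window=60.0)
        assert np.abs(twice.raster - once.raster).max() < 0.02

    def test_window_validation(self):
        field = FieldImage(np.zeros((1, 50, 50), dtype=np.float32), 1.0,
                           ["DAPI"])
        with pytest.raises(ValueError, match="erase"):
            correct_background(field, window=10.0)
        with pytest.raises(ValueError, match="colony diameter"):
            correct_background(field, window=600.0)


class TestDetect:
    def test_three_colonies_recovered_near_truth(self):
        spec, field, truth = _field(5)
        regions = detect_colonies(field, 100.0)
        assert len(regions) == 3
        for want in truth.colony_centers:
            err = min(np.hypot(r.center[0] - want[0], r.center[1] - want[1])
                      for r in regions)
            assert err < 5.0

    def test_empty_field_yields_no_regions(self):
        field = FieldImage(np.zeros((1, 200, 200), dtype=np.float32), 1.0,
                           ["DAPI"])
        assert detect_colonies(field, 100.0) == []

    def test_merged_pair_is_a_single_region(self):
        spec = SceneSpec(seed=6, **DENSE)
        field, truth = generate_multicolony_field(
            spec, [(400.0, 400.0), (900.0, 400.0)], include_merged=True)
        regions = detect_colonies(field, 100.0)
        # merged blob + the isolated colony
        assert len(regions) == 2
        areas = sorted(r.area for r in regions)
        assert areas[1] > 1.6 * np.pi * 100.0 ** 2

    def test_translation_equivariance(self):
        """Shifting the whole layout shifts detected centres identically."""
        base = [(150.0, 150.0), (600.0, 150.0), (380.0, 560.0)]
        dx, dy = 40.0, 25.0
        _, f1, _ = _field(7, layout=base)
        _, f2, _ = _field(7, layout=[(x + dx, y + dy) for x, y in base])
        c1 = [r.center for r in detect_colonies(f1, 100.0)]
        c2 = [r.center for r in detect_colonies(f2, 100.0)]
        for (x1, y1), (x2, y2) in zip(c1, c2):
            assert np.hypot(x2 - x1 - dx, y2 - y1 - dy) < 1.5


class TestFilter:
    def test_isolated_disc_accepted_merged_rejected(self):
        spec = SceneSpec(seed=8, **DENSE)
        field, truth = generate_multicolony_field(
            spec, [(400.0, 400.0), (900.0, 400.0)], include_merged=True)
        regions = filter_colonies(detect_colonies(field, 100.0), 100.0)
        accepted = [r for r in regions if r.status == "accepted"]
        rejected = [r for r in regions if r.status == "rejected"]
        assert len(accepted) == 1 and len(rejected) == 1
        assert "area" in rejected[0].reason

    @pytest.mark.parametrize("seed", range(5))
    def test_merged_pair_never_accepted(self, seed):
        spec = SceneSpec(seed=100 + seed, **DENSE)
        field, truth = generate_multicolony_field(
            spec, [(400.0, 400.0), (900.0, 400.0)], include_merged=True)
        regions = filter_colonies(detect_colonies(field, 100.0), 100.0)
        big = max(regions, key=lambda r: r.area)
        assert big.status == "rejected"

    def test_half_cropped_edge_colony_rejected(self):
        spec, field, _ = _field(9, layout=[(150.0, 150.0), (600.0, 150.0),
                                           (380.0, 560.0)])
        cut = FieldImage(field.raster[:, :, 140:], 1.0,
                         list(field.channel_names))
        regions = filter_colonies(detect_colonies(cut, 100.0), 100.0)
        clipped = min(regions, key=lambda r: r.center[0])
        assert clipped.status == "rejected"


class TestExtract:
    def test_crop_contains_disc_and_roundtrips(self):
        spec, field, truth = _field(10)
        reg = filter_colonies(detect_colonies(field, 100.0), 100.0)[0]
        col = extract_colony(field, reg, 100.0)
        _, h, w = col.raster.shape
        assert min(h, w) * col.pixel_size >= 2 * 100.0
        # re-detection on the crop finds the same centre within a pixel
        sub = FieldImage(col.raster, col.pixel_size, col.channel_names)
        reg2 = detect_colonies(sub, 100.0)[0]
        assert np.hypot(reg2.center[0] - col.center[0],
                        reg2.center[1] - col.center[1]) < 5.0

    def test_rejected_region_refused(self):
        spec = SceneSpec(seed=11, **DENSE)
        field, _ = generate_multicolony_field(
            spec, [(400.0, 400.0), (900.0, 400.0)], include_merged=True)
        regions = filter_colonies(detect_colonies(field, 100.0), 100.0)
        bad = next(r for r in regions if r.status == "rejected")
        with pytest.raises(ValueError, match="rejected"):
            extract_colony(field, bad, 100.0)

    def test_corner_region_fails_bounds(self):
        spec, field, _ = _field(12)
        reg = detect_colonies(field, 100.0)[0]
        with pytest.raises(ValueError, match="bounds"):
            extract_colony(field, reg, 100.0, margin=200.0)
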