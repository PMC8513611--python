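"""Germ-layer domain segmentation, areas, and cohort-level changes."""

import numpy as np
import pytest

from gastruloid_quant.colony import ColonyImage
from gastruloid_quant.domains import (DOMAIN_LABELS, central_area_from_cells,
                                      domain_areas, relative_central_change,
                                      segment_domains)
from gastruloid_quant.geometry import alpha_shape, polygons_of
from gastruloid_quant.scenes import (CentralDisc, Ring, SceneSpec,
                                     generate_colony_image)


def _analytic_truth(colony, radii):
    h = colony.raster.shape[1]
    ys, xs = np.mgrid[0:h, 0:h]
    r = np.hypot(xs * colony.pixel_size - colony.center[0],
                 ys * colony.pixel_size - colony.center[1])
    tr = np.zeros((h, h), dtype=np.uint8)
    tr[r <= colony.analysis_radius] = DOMAIN_LABELS["outer"]
    tr[r <= radii[1]] = DOMAIN_LABELS["middle"]
    tr[r <= radii[0]] = DOMAIN_LABELS["central"]
    return tr


def _fine_spec(seed, central=120.0, middle=160.0, colony=250.0):
    """Fine-packed scene (3 µm nuclei): rim gaps small against the
    boundary-length-to-area ratio."""
    return SceneSpec(
        colony_radius=colony, density=9000.0, nucleus_radius=3.0,
        channel_models={"SOX2": CentralDisc(radius=central),
                        "BRA": Ring(r_in=central, r_out=middle)},
        seed=seed)


class TestSegmentation:
    def test_fine_packed_three_ring_accuracy(self):
        """≥95% per-pixel agreement with the generating geometry."""
        colony, _ = generate_colony_image(_fine_spec(31))
        dmap = segment_domains(colony, ["SOX2", "BRA"])
        truth = _analytic_truth(colony, (120.0, 160.0))
        ind = dmap.labels > 0
        assert (dmap.labels[ind] == truth[ind]).mean() >= 0.95
        assert dmap.ordering_ok

    def test_study_density_three_ring_accuracy(self, three_ring_colony):
        """≥90% at study packing (5 µm nuclei leave rim gaps)."""
        _, colony, _ = three_ring_colony
        dmap = segment_domains(colony, ["SOX2", "BRA"])
        truth = _analytic_truth(colony, (167.0, 220.0))
        ind = dmap.labels > 0
        assert (dmap.labels[ind] == truth[ind]).mean() >= 0.90

    def test_partition_is_exact(self, three_ring_colony):
        _, colony, _ = three_ring_colony
        dmap = segment_domains(colony, ["SOX2", "BRA"])
        disc = colony.disc_mask()
        counts = {k: int(np.sum(dmap.labels == v))
                  for k, v in DOMAIN_LABELS.items()}
        assert sum(counts.values()) == int(disc.sum())
        areas = domain_areas(dmap)
        fr = sum(areas[f"{k}_fraction"] for k in DOMAIN_LABELS)
        assert fr <= 1.0 + 1e-9

    def test_no_central_marker_gives_empty_central(self):
        spec = SceneSpec(
            colony_radius=150.0, density=3700.0,
            channel_models={"SOX2": CentralDisc(radius=0.0),
                            "BRA": Ring(r_in=0.0, r_out=120.0)},
            seed=32)
        colony, _ = generate_colony_image(spec)
        dmap = segment_domains(colony, ["SOX2", "BRA"])
        areas = domain_areas(dmap)
        assert areas["central_fraction"] < 0.02

    def test_rotation_leaves_areas_unchanged(self):
        colony, _ = generate_colony_image(_fine_spec(33))
        dmap = segment_domains(colony, ["SOX2", "BRA"])
        rot = ColonyImage(np.stack([np.rot90(c) for c in colony.raster]),
                          colony.center, colony.analysis_radius,
                          colony.pixel_size, list(colony.channel_names))
        dmap_r = segment_domains(rot, ["SOX2", "BRA"])
        a, b = domain_areas(dmap), domain_areas(dmap_r)
        for k in DOMAIN_LABELS:
            assert a[f"{k}_area_um2"] == pytest.approx(b[f"{k}_area_um2"],
                                                       rel=0.01)

    def test_degenerate_histogram_rejected(self):
        raster = np.full((2, 101, 101), 0.3, dtype=np.float32)
        colony = ColonyImage(raster, (50.0, 50.0), 40.0, 1.0,
                             ["SOX2", "BRA"])
        with pytest.raises(ValueError, match="not separable"):
            segment_domains(colony, ["SOX2", "BRA"])

    def test_needs_two_channels(self, three_ring_colony):
        _, colony, _ = three_ring_colony
        with pytest.raises(ValueError, match="two"):
            segment_domains(colony, ["SOX2"])


class TestAreas:
    @pytest.mark.parametrize("pixel_size", [1.0, 0.5])
    def test_alpha_shape_area_converges_to_disc(self, pixel_size):
        """Densely-filled disc of radius 167: alpha-shape + rasterized area
        within 3% of πr², approaching it as the pixel grid refines."""
        from gastruloid_quant.geometry import rasterize_polygon
        r = 167.0
        n = int(2 * (r + 10) / pixel_size)
        ys, xs = np.mgrid[0:n, 0:n]
        cx = (n - 1) / 2 * pixel_size
        rad = np.hypot(xs * pixel_size - cx, ys * pixel_size - cx)
        inside = rad <= r
        stride = max(int(round(2.0 / pixel_size)), 1)
        pts = np.column_stack([xs[inside], ys[inside]]) * pixel_size
        pts = pts[(np.arange(len(pts)) % stride) == 0]
        poly = polygons_of(alpha_shape(pts, 20.0))[0]
        mask = rasterize_polygon(poly, (n, n), pixel_size)
        area = mask.sum() * pixel_size ** 2
        assert area == pytest.approx(np.pi * r ** 2, rel=0.03)

    def test_central_fraction_for_half_radius_disc(self):
        """125 µm central disc on a 250 µm colony: fraction ≈ 1/4."""
        spec = SceneSpec(
            colony_radius=250.0, density=3700.0,
            channel_models={"SOX2": CentralDisc(radius=125.0),
                            "BRA": Ring(r_in=125.0, r_out=220.0)},
            seed=34)
        colony, _ = generate_colony_image(spec)
        areas = domain_areas(segment_domains(colony, ["SOX2", "BRA"]))
        assert areas["central_fraction"] == pytest.approx(0.25, abs=0.03)

    def test_cell_based_area_cross_checks_pixel_area(self, three_ring_colony):
        from gastruloid_quant.nuclei import segment_colony
        from gastruloid_quant.quant import (classify_positive,
                                            fit_binary_threshold,
                                            normalize_to_dapi)
        _, colony, _ = three_ring_colony
        cells, _ = segment_colony(colony)
        cells = normalize_to_dapi(cells, "SOX2")
        fit = fit_binary_threshold(cells["norm_SOX2"])
        cells = classify_positive(cells, "SOX2", fit)
        cell_area = central_area_from_cells(cells, "SOX2")
        px_area = domain_areas(
            segment_domains(colony, ["SOX2", "BRA"]))["central_area_um2"]
        assert cell_area == pytest.approx(px_area, rel=0.10)


class TestRelativeChange:
    def test_identical_cohorts_change_zero(self):
        out = relative_central_change([3.0, 4.0], [3.0, 4.0])
        assert out["percent_change"] == 0.0

    def test_antisymmetry_identity(self, rng):
        a = rng.uniform(1.0, 2.0, 10)
        b = rng.uniform(2.0, 4.0, 10)
        ab = relative_central_change(a, b)["percent_change"]
        ba = relative_central_change(b, a)["percent_change"]
        assert ab == pytest.approx(-ba * a.mean() / b.mean(), rel=1e-9)

    def test_reference_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            relative_central_change([1.0], [0.0])

    def test_normalized_scatter_values_returned(self):
        out = relative_central_change([2.0, 2.0], [1.0, 3.0])
        assert out["test_normalized"] == [0.0, 0.0]
        assert out["reference_normalized"] == [-50.0, 50.0]
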