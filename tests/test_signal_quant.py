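"""Normalization, thresholding, classification, and radial statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gastruloid_quant.quant import (center_edge_summary, classify_positive,
                                    fit_binary_threshold, fraction_positive,
                                    normalize_to_dapi, radial_profile,
                                    ring_width, secretor_proximity)


def _table(n, rng, radial_max=250.0):
    r = radial_max * np.sqrt(rng.random(n))
    th = 2 * np.pi * rng.random(n)
    return pd.DataFrame({
        "nucleus_id": np.arange(n),
        "x_um": 250 + r * np.cos(th),
        "y_um": 250 + r * np.sin(th),
        "radial_um": r,
        "area_um2": np.full(n, 78.5),
    })


def _two_class_cells(n, frac, lo, hi, sd, rng, radial_rule=None):
    cells = _table(n, rng)
    if radial_rule is None:
        lab = (rng.random(n) < frac).astype(int)
    else:
        lab = radial_rule(cells["radial_um"].to_numpy()).astype(int)
    vals = np.where(lab == 1, hi, lo) + rng.standard_normal(n) * sd
    cells["median_DAPI"] = 1.0
    cells["median_M"] = vals
    return cells, lab


class TestNormalize:
    def test_dapi_over_dapi_is_one(self, rng):
        cells = _table(30, rng)
        cells["median_DAPI"] = rng.uniform(0.5, 2.0, 30)
        out = normalize_to_dapi(cells, "DAPI")
        assert np.allclose(out["norm_DAPI"], 1.0)

    def test_ratio_and_zero_dapi_drop(self, rng):
        cells = _table(10, rng)
        cells["median_DAPI"] = np.r_[np.full(9, 0.5), 0.0]
        cells["median_M"] = 1.0
        out = normalize_to_dapi(cells, "M")
        assert len(out) == 9
        assert np.allclose(out["norm_M"], 2.0)


class TestThreshold:
    def test_balanced_mixture_threshold_between_modes(self, rng):
        vals = np.r_[rng.normal(0.2, 0.05, 500), rng.normal(0.8, 0.05, 500)]
        fit = fit_binary_threshold(vals)
        # symmetric case: the Bayes boundary is 0.5 by construction
        assert 0.4 <= fit.threshold <= 0.6
        assert fit.converged
        assert fit.means[0] < fit.threshold < fit.means[1]

    def test_unimodal_sample_flagged(self, rng):
        fit = fit_binary_threshold(rng.normal(0.5, 0.05, 300))
        assert not fit.converged

    def test_minority_weight_recovered(self, rng):
        vals = np.r_[rng.normal(0.2, 0.05, 800), rng.normal(0.8, 0.05, 200)]
        fit = fit_binary_threshold(vals)
        assert fit.weights[1] == pytest.approx(0.20, abs=0.03)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="20"):
            fit_binary_threshold(np.ones(10))


class TestClassify:
    def test_tie_at_threshold_is_negative(self, rng):
        cells, _ = _two_class_cells(50, 0.5, 0.2, 0.8, 0.0, rng)
        cells = normalize_to_dapi(cells, "M")
        fit = fit_binary_threshold(cells["norm_M"])
        cells.loc[cells.index[0], "norm_M"] = fit.threshold
        out = classify_positive(cells, "M", fit)
        assert not out.iloc[0]["positive_M"]

    def test_noise_free_calls_match_truth(self, rng):
        cells, lab = _two_class_cells(200, 0.3, 0.2, 0.8, 0.0, rng)
        cells = normalize_to_dapi(cells, "M")
        fit = fit_binary_threshold(cells["norm_M"])
        out = classify_positive(cells, "M", fit)
        assert np.array_equal(out["positive_M"].to_numpy(), lab == 1)

    def test_error_rate_within_two_points_of_bayes(self, rng):
        """Monte-Carlo Bayes-error oracle bounds the classifier error."""
        lo, hi = 0.2, 0.8
        sd = 0.25 * (hi - lo)
        cells, lab = _two_class_cells(4000, 0.5, lo, hi, sd, rng)
        cells = normalize_to_dapi(cells, "M")
        fit = fit_binary_threshold(cells["norm_M"])
        out = classify_positive(cells, "M", fit)
        err = (out["positive_M"].to_numpy() != (lab == 1)).mean()
        # oracle: optimal midpoint rule on a fresh Monte-Carlo draw
        m = 200_000
        olab = rng.random(m) < 0.5
        ovals = np.where(olab, hi, lo) + rng.standard_normal(m) * sd
        bayes = ((ovals > (lo + hi) / 2) != olab).mean()
        assert err <= bayes + 0.02

    def test_missing_normalized_column_rejected(self, rng):
        cells, _ = _two_class_cells(30, 0.5, 0.2, 0.8, 0.0, rng)
        fit = fit_binary_threshold(np.r_[np.full(15, 0.2), np.full(15, 0.8)])
        with pytest.raises(ValueError, match="norm"):
            classify_positive(cells, "M", fit)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_global_intensity_scaling_leaves_calls_unchanged(self, scale):
        """Normalize→threshold→classify is invariant to a global gain."""
        rng = np.random.default_rng(77)
        cells, _ = _two_class_cells(300, 0.4, 0.2, 0.8, 0.03, rng)
        base = normalize_to_dapi(cells, "M")
        fit = fit_binary_threshold(base["norm_M"])
        calls = classify_positive(base, "M", fit)["positive_M"].to_numpy()

        scaled = cells.copy()
        scaled["median_DAPI"] *= scale
        scaled["median_M"] *= scale
        s = normalize_to_dapi(scaled, "M")
        sfit = fit_binary_threshold(s["norm_M"])
        scalls = classify_positive(s, "M", sfit)["positive_M"].to_numpy()
        assert np.array_equal(calls, scalls)


class TestRadialProfile:
    def test_uniform_channel_is_flat(self, rng):
        cells = _table(2000, rng)
        cells["v"] = 1.0 + 0.02 * rng.standard_normal(2000)
        prof = radial_profile(cells, analysis_radius=250.0, bin_width=10.0,
                              value_column="v")
        ok = prof.n >= 2
        spread = prof.mean[ok].max() - prof.mean[ok].min()
        assert spread < 2 * np.nanmax(prof.sd[ok])

    def test_edge_band_transition_location(self, rng):
        cells, _ = _two_class_cells(
            3000, None, 0.0, 1.0, 0.0, rng,
            radial_rule=lambda r: r >= 170.0)
        prof = radial_profile(cells, analysis_radius=250.0, bin_width=10.0,
                              value_column="median_M")
        assert prof.mean[prof.bin_centers < 160].max() < 0.1
        assert prof.mean[prof.bin_centers > 180].min() > 0.9

    def test_pixel_mode_agrees_with_cell_mode(self, small_colony):
        """Cross-oracle: nuclear-pixel profile vs per-cell-median profile.

        The pixel oracle samples eroded nuclear interiors (the anti-aliased
        rim belongs to neither class) and skips the one bin containing the
        band edge, where centroid- and pixel-based assignment legitimately
        differ.
        """
        from scipy.ndimage import binary_erosion

        from gastruloid_quant.nuclei import segment_colony
        spec, colony, _ = small_colony
        cells, labels = segment_colony(colony)
        cprof = radial_profile(cells, analysis_radius=150.0, bin_width=15.0,
                               value_column="median_MARKER")
        pprof = radial_profile(colony.channel("MARKER"), center=colony.center,
                               analysis_radius=150.0, bin_width=15.0,
                               mask=binary_erosion(labels > 0))
        band_edge = 100.0
        ok = ((cprof.n > 0) & (pprof.n > 0)
              & (np.abs(cprof.bin_centers - band_edge) > cprof.bin_width))
        rel = np.abs(cprof.mean[ok] - pprof.mean[ok]) / pprof.mean[ok]
        assert rel.max() < 0.05

    def test_empty_bins_are_null_not_interpolated(self):
        cells = pd.DataFrame({"radial_um": [5.0, 95.0], "v": [1.0, 2.0]})
        prof = radial_profile(cells, analysis_radius=100.0, bin_width=10.0,
                              value_column="v")
        assert prof.n[4] == 0 and np.isnan(prof.mean[4])

    def test_bin_width_bounds(self, rng):
        cells = _table(50, rng)
        cells["v"] = 1.0
        with pytest.raises(ValueError, match="bin_width"):
            radial_profile(cells, bin_width=1.0, value_column="v")

    def test_count_weighted_mean_conserved(self, rng):
        """Conservation: n-weighted bin means equal the global mean."""
        cells = _table(1500, rng)
        cells["v"] = rng.uniform(0.0, 2.0, 1500)
        prof = radial_profile(cells, analysis_radius=250.0, bin_width=10.0,
                              value_column="v")
        ok = prof.n > 0
        weighted = np.sum(prof.mean[ok] * prof.n[ok]) / prof.n[ok].sum()
        assert weighted == pytest.approx(cells["v"].mean(), rel=1e-9)


class TestRingWidth:
    @staticmethod
    def _profile_for(activation_radius, rng, n=3000):
        cells, _ = _two_class_cells(
            n, None, 0.1, 1.0, 0.0, rng,
            radial_rule=lambda r: r >= activation_radius)
        return radial_profile(cells, analysis_radius=250.0, bin_width=10.0,
                              value_column="median_M")

    def test_edge_activation_at_170_gives_80(self, rng):
        prof = self._profile_for(170.0, rng)
        width, flag = ring_width(prof, 250.0)
        assert flag == "ok"
        assert width == pytest.approx(80.0, abs=10.0)

    def test_uniformly_positive_colony_is_full_radius(self, rng):
        cells = _table(500, rng)
        cells["v"] = 1.0
        prof = radial_profile(cells, analysis_radius=250.0, bin_width=10.0,
                              value_column="v")
        width, flag = ring_width(prof, 250.0)
        assert width == 250.0 and flag == "ok"

    def test_width_monotone_in_true_ring(self, rng):
        widths = [ring_width(self._profile_for(250.0 - w, rng), 250.0)[0]
                  for w in (40.0, 80.0, 120.0)]
        assert widths[0] < widths[1] < widths[2]

    def test_all_negative_profile_flags_no_ring(self, rng):
        cells = _table(500, rng)
        cells["v"] = 0.0
        prof = radial_profile(cells, analysis_radius=250.0, bin_width=10.0,
                              value_column="v")
        width, flag = ring_width(prof, 250.0)
        assert width == 0.0 and flag == "no ring"

    def test_needs_ten_bins(self, rng):
        cells = _table(100, rng, radial_max=40.0)
        cells["v"] = 1.0
        prof = radial_profile(cells, analysis_radius=50.0, bin_width=10.0,
                              value_column="v")
        with pytest.raises(ValueError, match="10"):
            ring_width(prof, 50.0)


class TestCenterEdge:
    def test_uniform_equal_within_noise(self, rng):
        cells = _table(2000, rng)
        cells["v"] = 1.0 + 0.05 * rng.standard_normal(2000)
        s = center_edge_summary(cells, "v")
        pooled = np.hypot(s["center_sd"] / np.sqrt(s["n_center"]),
                          s["edge_sd"] / np.sqrt(s["n_edge"]))
        assert abs(s["center_mean"] - s["edge_mean"]) < 4 * pooled

    def test_edge_band_contrast(self, rng):
        cells, _ = _two_class_cells(
            2000, None, 0.2, 1.0, 0.0, rng,
            radial_rule=lambda r: r >= 200.0)
        s = center_edge_summary(cells, "median_M")
        assert s["edge_mean"] - s["center_mean"] == pytest.approx(0.8,
                                                                  abs=0.05)

    def test_tiny_colony_fails_on_empty_edge_band(self, rng):
        cells = _table(100, rng, radial_max=80.0)
        cells["v"] = 1.0
        with pytest.raises(ValueError, match="edge"):
            center_edge_summary(cells, "v", analysis_radius=250.0)

    def test_overlapping_bands_rejected(self, rng):
        cells = _table(100, rng)
        cells["v"] = 1.0
        with pytest.raises(ValueError, match="overlap"):
            center_edge_summary(cells, "v", center_radius=220.0,
                                edge_band=50.0)


class TestFractionPositive:
    def test_truth_labels_give_exact_fraction(self, rng):
        cells, lab = _two_class_cells(700, None, 0.2, 0.8, 0.0, rng,
                                      radial_rule=lambda r: r < 120.0)
        cells["positive_M"] = lab == 1
        out = fraction_positive(cells, "M")
        assert out["fraction"] == (lab == 1).mean()
        assert out["n"] == 700

    @pytest.mark.parametrize("frac", [0.05, 0.2, 0.5, 0.8])
    def test_estimated_fraction_across_sweep(self, frac):
        """Post-classification estimate within ±0.03 of truth at n=1000."""
        rng = np.random.default_rng(int(frac * 100))
        lo, hi = 0.2, 1.0
        sd = (hi - lo) / 4
        n = 1000
        lab = np.zeros(n, dtype=int)
        lab[rng.choice(n, int(frac * n), replace=False)] = 1
        cells = _table(n, rng)
        cells["median_DAPI"] = 1.0
        cells["median_M"] = np.where(lab == 1, hi, lo) \
            + rng.standard_normal(n) * sd
        cells = normalize_to_dapi(cells, "M")
        fit = fit_binary_threshold(cells["norm_M"])
        cells = classify_positive(cells, "M", fit)
        est = fraction_positive(cells, "M")["fraction"]
        assert est == pytest.approx(frac, abs=0.03)

    def test_empty_table_rejected(self):
        cells = pd.DataFrame({"positive_M": []})
        with pytest.raises(ValueError, match="empty"):
            fraction_positive(cells, "M")


class TestSecretorProximity:
    @staticmethod
    def _cells_with_secretors(rng, secretor_xy, boundary, n=2000):
        cells = _table(n, rng, radial_max=250.0)
        spts = np.asarray(secretor_xy)
        d = np.sqrt(((cells[["x_um", "y_um"]].to_numpy()[:, None, :]
                      - spts[None, :, :]) ** 2).sum(-1)).min(axis=1)
        cells["positive_SEC"] = False
        cells["median_R"] = np.where(d > boundary, 1.0, 0.1)
        sec = pd.DataFrame({
            "nucleus_id": np.arange(n, n + len(spts)),
            "x_um": spts[:, 0], "y_um": spts[:, 1],
            "radial_um": np.hypot(spts[:, 0] - 250, spts[:, 1] - 250),
            "area_um2": 78.5, "positive_SEC": True, "median_R": 0.0})
        return pd.concat([cells, sec], ignore_index=True), d

    def test_range_recovered_and_distances_match_brute_force(self, rng):
        """Two secretor clusters; KD-tree distances vs all-pairs minimum."""
        secretors = [(150.0, 250.0), (350.0, 250.0), (352.0, 255.0)]
        cells, d_oracle = self._cells_with_secretors(rng, secretors, 80.0)
        prof, rng_um, flag = secretor_proximity(cells, "SEC", "R",
                                                bin_width=10.0)
        assert flag == "ok"
        assert rng_um == pytest.approx(80.0, abs=10.0)
        # binned counts must match the brute-force distance histogram
        edges = np.arange(len(prof.n) + 1) * prof.bin_width
        counts, _ = np.histogram(d_oracle[d_oracle <= edges[-1]], bins=edges)
        assert np.array_equal(prof.n, counts)

    def test_no_suppression_flags_no_inhibition(self, rng):
        cells, _ = self._cells_with_secretors(rng, [(250.0, 250.0)], -1.0)
        _, rng_um, flag = secretor_proximity(cells, "SEC", "R")
        assert rng_um == 0.0 and flag == "no inhibition"

    def test_no_secretors_is_an_error(self, rng):
        cells = _table(50, rng)
        cells["positive_SEC"] = False
        cells["median_R"] = 1.0
        with pytest.raises(ValueError, match="no secretor"):
            secretor_proximity(cells, "SEC", "R")
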