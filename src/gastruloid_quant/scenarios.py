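"""Reference synthetic experiments run end-to-end through the pipeline.

Each function here builds a synthetic scene whose generating geometry is
chosen so that the pipeline's output has a known expected value, runs the
full measurement chain (segmentation → normalization → classification →
spatial statistic), and returns the measured quantity.  They are shared
by the analysis drivers, the test suite, and the acceptance script.

Geometries emulated:

* an edge-restricted signaling ring 80 µm wide (activation at radial
  positions ≥ 170 µm on a 250 µm colony at live-imaging nuclear packing);
* three-ring germ-layer colonies with prescribed central-domain radii,
  compared between cohorts as a percent area change;
* a transwell monolayer sheet of 700 nuclei with 140 responding (20%);
* a central cluster of ligand-secreting cells whose suppression zone ends
  200 µm from the nearest secretor.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .domains import domain_areas, relative_central_change, segment_domains
from .nuclei import segment_colony
from .quant import (classify_positive, fit_binary_threshold, fraction_positive,
                    normalize_to_dapi, radial_profile, ring_width,
                    secretor_proximity)
from .scenes import (CentralDisc, EdgeBand, IntensityModel, Ring, SceneSpec,
                     SecretorSpec, generate_colony_image,
                     generate_transwell_field)

__all__ = [
    "subseed",
    "match_to_truth",
    "edge_ring_spec",
    "measure_edge_ring_width",
    "three_ring_spec",
    "measure_central_area",
    "central_reduction",
    "transwell_spec",
    "measure_transwell_fraction",
    "measure_secretor_range",
]

#: nuclear packing of the live-imaging colonies: 683-785 nuclei per
#: 250 µm-radius colony ⇒ ~3700 nuclei/mm² at the midpoint
LIVE_PACKING_DENSITY = 3700.0


def subseed(seed: int, *idx: int) -> int:
    """Deterministic child seed (< 2^31) from a base seed and indices."""
    return int(np.random.SeedSequence([seed, *idx]).generate_state(1)[0]
               % (2 ** 31))


def match_to_truth(cells, truth, max_dist: float = 5.0):
    """Align segmented cells to ground-truth nuclei by nearest centroid.

    Returns (cells_subset, truth_subset) restricted to matches within
    ``max_dist`` µm, one-to-one by construction of the minimum packing
    separation.
    """
    tree = cKDTree(truth.nuclei[["x_um", "y_um"]].to_numpy())
    dist, idx = tree.query(cells[["x_um", "y_um"]].to_numpy())
    ok = dist <= max_dist
    return cells.loc[ok], truth.nuclei.iloc[idx[ok]]


# ---------------------------------------------------------------------------
# edge-restricted signaling ring
# ---------------------------------------------------------------------------


def edge_ring_spec(seed: int, activation_radius: float = 170.0,
                   colony_radius: float = 250.0,
                   n_nuclei: int = 700) -> SceneSpec:
    """Colony whose response channel is positive at radius ≥ activation_radius."""
    width = colony_radius - activation_radius
    return SceneSpec(
        colony_radius=colony_radius,
        n_nuclei=n_nuclei,
        channel_models={"pSMAD1": EdgeBand(width=width,
                                           colony_radius=colony_radius)},
        seed=seed,
    )


def measure_edge_ring_width(seed: int, activation_radius: float = 170.0,
                            bin_width: float = 10.0) -> float:
    """Segmentation → normalization → cell-mode profile → half-max width."""
    spec = edge_ring_spec(seed, activation_radius)
    colony, _ = generate_colony_image(spec)
    cells, _ = segment_colony(colony)
    cells = normalize_to_dapi(cells, "pSMAD1")
    fit = fit_binary_threshold(cells["norm_pSMAD1"])
    cells = classify_positive(cells, "pSMAD1", fit)
    prof = radial_profile(cells, analysis_radius=spec.colony_radius,
                          bin_width=bin_width, value_column="norm_pSMAD1")
    width, flag = ring_width(prof, spec.colony_radius)
    if flag != "ok":
        raise RuntimeError(f"unexpected ring flag: {flag}")
    return width


# ---------------------------------------------------------------------------
# three-ring germ-layer colonies
# ---------------------------------------------------------------------------


def three_ring_spec(seed: int, central_radius: float,
                    middle_outer_radius: float = 220.0,
                    colony_radius: float = 250.0) -> SceneSpec:
    """Central SOX2 disc, BRA ring, CDX2 edge band (standard patterning)."""
    return SceneSpec(
        colony_radius=colony_radius,
        density=LIVE_PACKING_DENSITY,
        channel_models={
            "SOX2": CentralDisc(radius=central_radius),
            "BRA": Ring(r_in=central_radius, r_out=middle_outer_radius),
            "CDX2": EdgeBand(width=colony_radius - middle_outer_radius,
                             colony_radius=colony_radius),
        },
        seed=seed,
    )


def measure_central_area(seed: int, central_radius: float) -> float:
    """Pixel-based central-domain area (µm²) of one synthetic colony."""
    colony, _ = generate_colony_image(three_ring_spec(seed, central_radius))
    dmap = segment_domains(colony, ["SOX2", "BRA"])
    return domain_areas(dmap)["central_area_um2"]


def central_reduction(r_reference: float, r_test: float, seed: int,
                      n_colonies: int = 10) -> dict:
    """Percent change in mean central-domain area between two cohorts."""
    ref = [measure_central_area(subseed(seed, 0, i), r_reference)
           for i in range(n_colonies)]
    test = [measure_central_area(subseed(seed, 1, i), r_test)
            for i in range(n_colonies)]
    return relative_central_change(test, ref)


# ---------------------------------------------------------------------------
# transwell monolayer fraction
# ---------------------------------------------------------------------------


def transwell_spec(seed: int, n_nuclei: int = 700,
                   class_separation_sd: float = 4.0) -> SceneSpec:
    """Monolayer sheet with class means separated by the stated # of sds.

    Class means sit well above zero so that the per-nucleus intensity
    jitter stays approximately Gaussian after the detector's clip at 0
    (a low mean comparable to its sd would pile probability mass at zero
    and break the two-class model the scene is meant to realize).
    """
    sd = (1.2 - 0.4) / class_separation_sd
    return SceneSpec(
        colony_radius=250.0,          # sheet side = 2 × this
        n_nuclei=n_nuclei,
        intensity=IntensityModel(low=0.4, high=1.2, low_sd=sd, high_sd=sd),
        channel_intensity={"DAPI": IntensityModel(low=0.4, high=1.2)},
        seed=seed,
    )


def measure_transwell_fraction(seed: int, n_nuclei: int = 700,
                               n_positive: int = 140) -> float:
    """Full classification pipeline on a transwell sheet; returns fraction."""
    spec = transwell_spec(seed, n_nuclei)
    img, _ = generate_transwell_field(spec, n_positive=n_positive,
                                      response_channel="SMAD23",
                                      layout="sheet")
    cells, _ = segment_colony(img)
    cells = normalize_to_dapi(cells, "SMAD23")
    fit = fit_binary_threshold(cells["norm_SMAD23"])
    cells = classify_positive(cells, "SMAD23", fit)
    return fraction_positive(cells, "SMAD23")["fraction"]


# ---------------------------------------------------------------------------
# secretor proximity
# ---------------------------------------------------------------------------


def measure_secretor_range(seed: int, suppression_radius: float = 200.0,
                           cluster_radius: float = 10.0,
                           bin_width: float = 10.0) -> float:
    """Inhibition range around a central secretor cluster.

    Secretor nuclei sit within ``cluster_radius`` of the colony centre and
    the response channel recovers beyond ``suppression_radius`` of the
    nearest secretor, so the half-max recovery distance should equal
    ``suppression_radius``.
    """
    spec = SceneSpec(
        colony_radius=250.0,
        n_nuclei=700,
        seed=seed,
    )
    secretors = SecretorSpec(n_secretors=3, cluster_radius=cluster_radius,
                             suppression_radius=suppression_radius,
                             channel="NOG")
    img, _ = generate_transwell_field(spec, response_channel="pSMAD1",
                                      secretors=secretors, layout="disc")
    cells, _ = segment_colony(img)
    cells = normalize_to_dapi(cells, "pSMAD1")
    cells = normalize_to_dapi(cells, "NOG")
    sec_fit = fit_binary_threshold(cells["norm_NOG"])
    cells = classify_positive(cells, "NOG", sec_fit)
    _, rng_um, flag = secretor_proximity(cells, "NOG", "pSMAD1",
                                         bin_width=bin_width)
    if flag != "ok":
        raise RuntimeError(f"unexpected secretor flag: {flag}")
    return rng_um
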