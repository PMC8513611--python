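"""Germ-layer domain segmentation and domain-area statistics.

A BMP4-patterned colony organizes into three concentric domains (central
ectoderm-like, middle mesoderm-like ring, outer extraembryonic-like edge).
Pixels inside the analysis disc are segmented by multi-Otsu thresholding
of marker intensities — the first marker (e.g. SOX2) defines the central
domain, the second (e.g. BRA) the middle ring — and each domain's solid
footprint is delineated with an alpha shape so that the inter-nuclear gaps
are closed.  Domain areas are pixel counts × pixel area; cohort-level
changes are expressed relative to the mean central-domain area of a
reference cohort, as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_multiotsu
from .colony import ColonyImage
from .geometry import alpha_shape, polygons_of, rasterize_polygon

__all__ = [
    "DomainMap",
    "DOMAIN_LABELS",
    "segment_domains",
    "domain_areas",
    "relative_central_change",
    "central_area_from_cells",
]

DOMAIN_LABELS = {"outer": 1, "middle": 2, "central": 3}


@dataclass
class DomainMap:
    """Per-pixel germ-layer domain labels within the analysis disc.

    ``labels``: 0 outside the disc, else DOMAIN_LABELS values; the three
    domains partition the disc exactly.  ``ordering_ok`` is False when the
    central domain is not innermost by mean radius (flagged, not fixed).
    """

    labels: np.ndarray
    pixel_size: float
    analysis_radius: float
    ordering_ok: bool = True

    @property
    def analysis_area(self) -> float:
        return float(np.pi * self.analysis_radius ** 2)


def _solidify(mask: np.ndarray, pixel_size: float, alpha: float,
              min_area_um2: float, disc: np.ndarray,
              largest_only: bool = False) -> np.ndarray:
    """Close a scattered marker-positive mask into a solid footprint.

    The small-component cutoff applies to the closed footprint polygons,
    not the raw pixels (individual nuclei must survive until the alpha
    shape has merged them).
    """
    ys, xs = np.nonzero(mask)
    if len(ys) < 3:
        return np.zeros_like(mask)
    stride = max(int(round(2.0 / pixel_size)), 1)
    keep = (ys % stride == 0) & (xs % stride == 0)
    if keep.sum() < 3:
        keep[:] = True
    pts = np.column_stack([xs[keep], ys[keep]]) * pixel_size
    shape = alpha_shape(pts, alpha)
    polys = polygons_of(shape)
    if not polys:
        return np.zeros_like(mask)
    if largest_only:
        polys = polys[:1]
    out = np.zeros_like(mask)
    for poly in polys:
        if poly.area < min_area_um2:
            continue
        out |= rasterize_polygon(poly, mask.shape, pixel_size, mask=disc)
    return out & disc


def _positive_pixels(ch: np.ndarray, disc: np.ndarray,
                     degenerate: str = "empty") -> np.ndarray:
    """Marker-positive pixels inside the disc via three-class multi-Otsu.

    Classes are background / marker-negative nuclei / marker-positive
    nuclei; the top class counts as positive only if the nuclear pixel
    intensities (above the background cut) are actually bimodal — a
    colony without the marker otherwise gets its nucleus class split in
    half.  ``degenerate`` controls the no-positive-population outcome:
    an empty mask or a "domains not separable" error.
    """
    from .quant import fit_binary_threshold

    vals = ch[disc]
    if np.ptp(vals) == 0:
        if degenerate == "raise":
            raise ValueError("domains not separable: degenerate intensity "
                             "histogram")
        return np.zeros_like(disc)
    try:
        thr = threshold_multiotsu(vals, classes=3)
    except ValueError as exc:  # fewer than 3 distinct grey levels
        if degenerate == "raise":
            raise ValueError("domains not separable: degenerate intensity "
                             "histogram") from exc
        return np.zeros_like(disc)
    # QC at the per-nucleus scale: mean intensity per connected nuclear
    # component must be bimodal, else there is no positive population
    # (raw pixel histograms always carry an anti-aliased rim mode)
    from scipy import ndimage

    nuclear_mask = ndimage.binary_erosion((ch > thr[0]) & disc)
    lbl, n = ndimage.label(nuclear_mask)
    if n >= 20:
        idx = np.arange(1, n + 1)
        sums = ndimage.sum_labels(ch, lbl, idx)
        counts = ndimage.sum_labels(np.ones_like(ch), lbl, idx)
        if not fit_binary_threshold(sums / counts).converged:
            return np.zeros_like(disc)
    return (ch > thr[1]) & disc


def segment_domains(colony: ColonyImage, channels,
                    alpha: float = 20.0,
                    min_component_um2: float = 50.0) -> DomainMap:
    """Three-domain segmentation of one colony.

    ``channels`` orders the markers centre→edge (e.g. ``["SOX2", "BRA"]``).
    Each marker is split into three intensity classes by multi-Otsu
    (background / marker-negative nuclei / marker-positive nuclei) within
    the analysis disc, and a two-Gaussian bimodality check on the nuclear
    pixels guards against calling a domain when the marker has no positive
    population.  The first marker's top class, solidified by an alpha
    shape, is the central domain; the second marker's gives the middle
    ring; the remaining disc pixels are the outer domain.  Components
    smaller than ``min_component_um2`` are absorbed into the surrounding
    label.
    """
    if len(channels) < 2:
        raise ValueError("at least two marker channels are required")
    disc = colony.disc_mask()
    px = colony.pixel_size

    ch1 = colony.channel(channels[0]).astype(np.float64)
    if np.ptp(ch1[disc]) == 0:
        raise ValueError("domains not separable: degenerate intensity "
                         "histogram")
    central_px = _positive_pixels(ch1, disc, degenerate="raise")
    central = _solidify(central_px, px, alpha, min_component_um2, disc,
                        largest_only=True)

    ch2 = colony.channel(channels[1]).astype(np.float64)
    middle_px = _positive_pixels(ch2, disc, degenerate="empty") & ~central
    middle = _solidify(middle_px, px, alpha, min_component_um2, disc)
    middle &= ~central

    labels = np.zeros(disc.shape, dtype=np.uint8)
    labels[disc] = DOMAIN_LABELS["outer"]
    labels[middle] = DOMAIN_LABELS["middle"]
    labels[central] = DOMAIN_LABELS["central"]

    # identity check: the central domain must be innermost by mean radius
    ordering_ok = True
    ys, xs = np.nonzero(labels > 0)
    r = np.hypot(xs * px - colony.center[0], ys * px - colony.center[1])
    lab = labels[ys, xs]
    r_central = r[lab == DOMAIN_LABELS["central"]]
    r_rest = r[lab != DOMAIN_LABELS["central"]]
    if r_central.size and r_rest.size and r_central.mean() > r_rest.mean():
        ordering_ok = False

    return DomainMap(labels=labels, pixel_size=px,
                     analysis_radius=colony.analysis_radius,
                     ordering_ok=ordering_ok)


def domain_areas(dmap: DomainMap) -> dict:
    """Per-domain area (µm²) and fraction of the analysis disc area."""
    out = {}
    for name, code in DOMAIN_LABELS.items():
        area = float(np.sum(dmap.labels == code)) * dmap.pixel_size ** 2
        out[f"{name}_area_um2"] = area
        out[f"{name}_fraction"] = area / dmap.analysis_area
    return out


def relative_central_change(test_areas, reference_areas) -> dict:
    """Percent change of the test-cohort mean central area vs the reference.

    Returns the summary percentage plus per-colony values normalized to
    the reference mean (for scatter output).
    """
    test = np.asarray(test_areas, dtype=float)
    ref = np.asarray(reference_areas, dtype=float)
    if test.size == 0 or ref.size == 0:
        raise ValueError("both cohorts must be non-empty")
    ref_mean = ref.mean()
    if ref_mean <= 0:
        raise ValueError("reference mean area must be positive")
    change = 100.0 * (test.mean() - ref_mean) / ref_mean
    return {
        "percent_change": float(change),
        "test_mean_um2": float(test.mean()),
        "reference_mean_um2": float(ref_mean),
        "test_normalized": (100.0 * (test - ref_mean) / ref_mean).tolist(),
        "reference_normalized": (100.0 * (ref - ref_mean) / ref_mean).tolist(),
    }


def central_area_from_cells(cells, channel: str,
                            alpha: float = 20.0) -> float:
    """Cross-check: central-domain area from classified cell positions.

    Alpha shape of the marker-positive cell centroids; provides an
    independent cell-based estimate of the pixel-based central area.
    """
    pos = cells.loc[cells[f"positive_{channel}"]]
    if len(pos) < 3:
        return 0.0
    shape = alpha_shape(pos[["x_um", "y_um"]].to_numpy(), alpha)
    polys = polygons_of(shape)
    return float(polys[0].area) if polys else 0.0
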