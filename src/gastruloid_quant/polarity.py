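"""Apicobasal polarity from z-stacks: ZO-1 apical surface and channel depths.

The tight-junction marker ZO-1 delineates the apical plane of the
epithelium.  Per lateral (x, y) position, the apical height is the
intensity-weighted mean z of the background-subtracted ZO-1 profile
(centroids are sub-plane accurate, unlike argmax); positions with too
little ZO-1 (e.g. junction gaps) are masked invalid and filled by smooth
interpolation.  Receptor or DNA channels are reduced to a depth the same
way, and the signed distance to the apical surface (positive = basal,
deeper in z) summarizes where a channel sits along the apicobasal axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian

__all__ = [
    "ApicalSurface",
    "PolarityDistribution",
    "interpolate_apical_surface",
    "distance_to_apical",
    "compare_polarity",
]


@dataclass
class ApicalSurface:
    """Interpolated apical z-height (µm) per lateral position."""

    z_height: np.ndarray        # (Y, X), µm
    valid: np.ndarray           # bool mask: sufficient ZO-1 signal
    z_step: float
    pixel_size: float


@dataclass
class PolarityDistribution:
    """Signed distance-to-apical (µm, positive = basal) per lateral position."""

    distances: np.ndarray       # masked to valid positions, 1D
    median: float
    q1: float
    q3: float
    n: int


def _weighted_depth(stack: np.ndarray, z_step: float,
                    rel_floor: float = 0.5):
    """Intensity-weighted mean z per lateral position, after per-profile
    background subtraction (10th percentile, clipped at 0) and a relative
    floor (planes below ``rel_floor`` × the profile peak carry no weight —
    residual noise over the full z range otherwise dominates the centroid
    variance at moderate SNR).

    Returns (depth, total_weight)."""
    z = np.arange(stack.shape[0]) * z_step
    bg = np.percentile(stack, 10, axis=0)
    prof = np.clip(stack - bg[None], 0.0, None)
    peak = prof.max(axis=0)
    prof = np.where(prof >= rel_floor * peak[None], prof, 0.0)
    total = prof.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        depth = np.tensordot(z, prof, axes=(0, 0)) / total
    return depth, total


def interpolate_apical_surface(zo1: np.ndarray, z_step: float,
                               pixel_size: float = 1.0,
                               noise_floor: Optional[float] = None,
                               smooth_um: float = 2.0) -> ApicalSurface:
    """Continuous apical surface from a ZO-1 z-stack channel (Z, Y, X).

    ``noise_floor`` is the minimum integrated (background-subtracted) ZO-1
    per position; positions below it are masked invalid and filled from
    their neighbours.  Default: 20% of the median integrated signal.  The
    surface is laterally smoothed with σ = ``smooth_um``.
    """
    if zo1.ndim != 3 or zo1.shape[0] < 5:
        raise ValueError("need a (Z, Y, X) stack with at least 5 planes")
    depth, total = _weighted_depth(zo1, z_step)
    if noise_floor is None:
        noise_floor = 0.2 * float(np.median(total))
    valid = total > max(noise_floor, 1e-12)
    if not valid.any():
        raise ValueError("no apical surface: entire stack below noise floor")

    height = depth.copy()
    if not valid.all():
        # nearest-neighbour fill of invalid patches, then smoothing below
        idx = ndimage.distance_transform_edt(
            ~valid, return_distances=False, return_indices=True)
        height = height[tuple(idx)]
    sigma = smooth_um / pixel_size
    if sigma > 0:
        height = gaussian(height, sigma=sigma, preserve_range=True)
    return ApicalSurface(z_height=height, valid=valid, z_step=z_step,
                         pixel_size=pixel_size)


def distance_to_apical(stack: np.ndarray, surface: ApicalSurface,
                       min_positions: int = 100) -> PolarityDistribution:
    """Signed distance of a channel's z-centroid from the apical surface.

    Positive distances are basal (deeper than the ZO-1 plane).  Positions
    invalid in the surface or with an all-background channel profile are
    excluded; a channel with no signal anywhere is an error.
    """
    if stack.shape[1:] != surface.z_height.shape:
        raise ValueError("stack geometry does not match the surface")
    depth, total = _weighted_depth(stack, surface.z_step)
    ok = surface.valid & (total > 1e-12) & np.isfinite(depth)
    if not ok.any():
        raise ValueError("channel contains no signal above background")
    dist = (depth - surface.z_height)[ok]
    if dist.size >= max(min_positions, 1):
        med = float(np.median(dist))
        q1, q3 = (float(q) for q in np.percentile(dist, [25, 75]))
    else:
        med = q1 = q3 = float("nan")
    return PolarityDistribution(distances=dist, median=med, q1=q1, q3=q3,
                                n=int(dist.size))


def compare_polarity(dists: dict) -> pd.DataFrame:
    """Summary table of per-condition distance distributions.

    ``dists`` maps condition name → PolarityDistribution; row order
    follows the input order.  No inference is performed here (group
    comparisons are delegated to the statistics layer).
    """
    if len(dists) < 2:
        raise ValueError("need at least two conditions to compare")
    rows = [{"condition": name, "median_um": d.median,
             "q1_um": d.q1, "q3_um": d.q3, "n_positions": d.n}
            for name, d in dists.items()]
    return pd.DataFrame(rows)
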