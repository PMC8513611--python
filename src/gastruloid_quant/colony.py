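"""Field assembly, background correction, and colony detection/extraction.

Workflow mirrors the standard micropattern pipeline: image tiles are
stitched with linear feather blending, a smooth background estimate is
subtracted per channel, colonies are detected by thresholding the smoothed
DAPI channel and delineating alpha-shape footprints scaled to colony size,
unusable colonies (merged, clipped, misshapen) are excluded with explicit
reasons, and each accepted colony is extracted as a square crop around its
centre with a declared analysis radius (250 µm for 500 µm disc patterns).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu

from .geometry import alpha_shape, polygons_of

__all__ = [
    "FieldImage",
    "ColonyRegion",
    "ColonyImage",
    "stitch_tiles",
    "correct_background",
    "detect_colonies",
    "filter_colonies",
    "extract_colony",
    "read_field",
    "write_colony",
    "write_manifest",
]


@dataclass
class FieldImage:
    """Calibrated multi-channel field raster (C, H, W)."""

    raster: np.ndarray
    pixel_size: float
    channel_names: list

    def __post_init__(self):
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 3:
            raise ValueError("field raster must be (C, H, W)")
        if len(self.channel_names) != self.raster.shape[0]:
            raise ValueError("channel_names must match raster channels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def channel(self, name: str) -> np.ndarray:
        return self.raster[self.channel_names.index(name)]


@dataclass
class ColonyRegion:
    """One detected colony candidate in field coordinates (µm)."""

    footprint: object                       # shapely Polygon
    center: tuple                           # (x, y) µm
    area: float                             # µm²
    effective_radius: float                 # sqrt(area/π), µm
    status: str = "detected"                # detected | accepted | rejected
    reason: Optional[str] = None


@dataclass
class ColonyImage:
    """Square multi-channel crop of one colony.

    ``center`` is in µm in the crop frame; the crop fully contains the
    disc of ``analysis_radius`` about it.
    """

    raster: np.ndarray
    center: tuple
    analysis_radius: float
    pixel_size: float
    channel_names: list

    def channel(self, name: str) -> np.ndarray:
        return self.raster[self.channel_names.index(name)]

    def disc_mask(self, radius: Optional[float] = None) -> np.ndarray:
        """Boolean mask of pixels within ``radius`` (default analysis radius)."""
        radius = self.analysis_radius if radius is None else radius
        _, h, w = self.raster.shape
        ys, xs = np.mgrid[0:h, 0:w]
        r = np.hypot(xs * self.pixel_size - self.center[0],
                     ys * self.pixel_size - self.center[1])
        return r <= radius


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------


def stitch_tiles(tiles, overlap: Optional[float] = None) -> FieldImage:
    """Reassemble a field from overlapping tiles with linear feathering.

    Accepts a :class:`~gastruloid_quant.scenes.TileSet` or a bare list of
    ``(row, col, y0_px, x0_px, array)`` records (then ``overlap``,
    pixel size 1 µm/px and generic channel names are assumed).  Each
    tile's contribution is weighted by a separable linear ramp over its
    overlapped margins, so per-pixel weights sum to one everywhere.
    """
    from .scenes import TileSet

    if isinstance(tiles, TileSet):
        records = tiles.tiles
        overlap = tiles.overlap
        pixel_size = tiles.pixel_size
        channel_names = list(tiles.channel_names)
        grid = tiles.grid_shape
    else:
        records = list(tiles)
        if overlap is None:
            raise ValueError("overlap fraction required for bare tile lists")
        pixel_size = 1.0
        channel_names = None
        rows = 1 + max(r for r, *_ in records)
        cols = 1 + max(c for _, c, *_ in records)
        grid = (rows, cols)

    slots = {(r, c) for r, c, *_ in records}
    for r in range(grid[0]):
        for c in range(grid[1]):
            if (r, c) not in slots:
                raise ValueError(f"missing tile at grid slot ({r}, {c})")
    shapes = {rec[4].shape for rec in records}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent tile shapes: {sorted(shapes)}")

    nch, th, tw = records[0][4].shape
    h = max(y0 + th for _, _, y0, _, _ in records)
    w = max(x0 + tw for _, _, _, x0, _ in records)
    acc = np.zeros((nch, h, w), dtype=np.float64)
    wacc = np.zeros((h, w), dtype=np.float64)

    margin_y = max(int(round(th * overlap)), 1)
    margin_x = max(int(round(tw * overlap)), 1)
    for r, c, y0, x0, arr in records:
        wy = np.ones(th)
        wx = np.ones(tw)
        if r > 0:
            wy[:margin_y] = np.linspace(0, 1, margin_y + 2)[1:-1]
        if r < grid[0] - 1:
            wy[-margin_y:] = np.linspace(1, 0, margin_y + 2)[1:-1]
        if c > 0:
            wx[:margin_x] = np.linspace(0, 1, margin_x + 2)[1:-1]
        if c < grid[1] - 1:
            wx[-margin_x:] = np.linspace(1, 0, margin_x + 2)[1:-1]
        wmap = wy[:, None] * wx[None, :]
        acc[:, y0:y0 + th, x0:x0 + tw] += arr * wmap
        wacc[y0:y0 + th, x0:x0 + tw] += wmap

    out = acc / np.where(wacc > 0, wacc, 1.0)
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(nch)]
    return FieldImage(raster=out.astype(np.float32), pixel_size=pixel_size,
                      channel_names=channel_names)


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------


def correct_background(field: FieldImage, window: float,
                       nucleus_radius: float = 5.0,
                       colony_radius: float = 250.0) -> FieldImage:
    """Subtract a smooth per-channel background estimate (clipped at 0).

    The background is a morphological (grey) opening with a flat window of
    ``window`` µm followed by Gaussian smoothing; the window must be large
    enough not to erase nuclei (≥ 4 nucleus radii) and no larger than one
    colony diameter (a larger window cannot track field-scale gradients).
    """
    if window < 4 * nucleus_radius:
        raise ValueError(
            f"background window {window} µm would erase nuclei "
            f"(minimum {4 * nucleus_radius} µm)")
    if window > 2 * colony_radius:
        raise ValueError(
            f"background window {window} µm exceeds one colony diameter")
    k = max(int(round(window / field.pixel_size)), 3)
    out = np.empty_like(field.raster, dtype=np.float32)
    for ci in range(field.raster.shape[0]):
        ch = field.raster[ci].astype(np.float64)
        bg = ndimage.grey_opening(ch, size=(k, k))
        bg = gaussian(bg, sigma=k / 4.0, preserve_range=True)
        out[ci] = np.clip(ch - bg, 0.0, None)
    return FieldImage(raster=out, pixel_size=field.pixel_size,
                      channel_names=list(field.channel_names))


# ---------------------------------------------------------------------------
# detection / filtering / extraction
# ---------------------------------------------------------------------------


def detect_colonies(field: FieldImage, expected_radius: float,
                    dapi_channel: str = "DAPI",
                    nucleus_radius: float = 5.0,
                    point_stride: Optional[int] = None) -> list:
    """Detect colony candidates from the DAPI channel.

    The DAPI channel is smoothed (σ ≈ nucleus radius), thresholded with
    Otsu, and the foreground pixel positions are closed into solid
    footprints by an alpha shape with α = expected_radius / 5 (scaling the
    closure to colony size).  Each footprint polygon whose area lies in
    [0.25, 4] × the expected disc area becomes a candidate region; its
    centre is the footprint centroid.  An empty field yields an empty list.
    """
    dapi = field.channel(dapi_channel).astype(np.float64)
    sigma = nucleus_radius / field.pixel_size
    sm = gaussian(dapi, sigma=sigma, preserve_range=True)
    if sm.max() <= 0 or np.allclose(sm, sm.flat[0]):
        return []
    thr = threshold_otsu(sm)
    fg = sm > thr
    if not fg.any():
        return []

    if point_stride is None:
        point_stride = max(int(round(nucleus_radius / field.pixel_size)), 1)
    ys, xs = np.nonzero(fg)
    keep = (ys % point_stride == 0) & (xs % point_stride == 0)
    pts = np.column_stack([xs[keep], ys[keep]]) * field.pixel_size

    alpha = expected_radius / 5.0
    shape = alpha_shape(pts, alpha)
    expected_area = np.pi * expected_radius ** 2
    regions = []
    for poly in polygons_of(shape):
        if not (0.25 * expected_area <= poly.area <= 4.0 * expected_area):
            continue
        cen = poly.centroid
        regions.append(ColonyRegion(
            footprint=poly,
            center=(cen.x, cen.y),
            area=poly.area,
            effective_radius=float(np.sqrt(poly.area / np.pi)),
        ))
    regions.sort(key=lambda r: (r.center[1], r.center[0]))
    return regions


def filter_colonies(regions: Sequence[ColonyRegion], expected_radius: float,
                    area_bounds: tuple = (0.5, 1.5),
                    min_circularity: float = 0.8) -> list:
    """Mark regions accepted or rejected (merged / clipped / misshapen).

    Rejection criteria: footprint area outside ``area_bounds`` × the
    expected disc area, or circularity 4πA/P² below ``min_circularity``.
    Every rejection carries a reason string.
    """
    expected_area = np.pi * expected_radius ** 2
    out = []
    for reg in regions:
        area_ratio = reg.area / expected_area
        perim = reg.footprint.length
        circ = 4 * np.pi * reg.area / perim ** 2 if perim > 0 else 0.0
        if area_ratio > area_bounds[1]:
            status, reason = "rejected", (
                f"area {area_ratio:.2f}x expected (merged colonies?)")
        elif area_ratio < area_bounds[0]:
            status, reason = "rejected", (
                f"area {area_ratio:.2f}x expected (partial colony?)")
        elif circ < min_circularity:
            status, reason = "rejected", f"circularity {circ:.2f} < {min_circularity}"
        else:
            status, reason = "accepted", None
        out.append(replace(reg, status=status, reason=reason))
    return out


def extract_colony(field: FieldImage, region: ColonyRegion,
                   analysis_radius: float,
                   margin: float = 10.0) -> ColonyImage:
    """Square crop centred on an accepted region.

    The crop side is 2 × (analysis_radius + margin); extraction fails if
    the crop would exceed the field bounds.
    """
    if region.status == "rejected":
        raise ValueError(f"cannot extract rejected region: {region.reason}")
    half_px = int(np.ceil((analysis_radius + margin) / field.pixel_size))
    cx = int(round(region.center[0] / field.pixel_size))
    cy = int(round(region.center[1] / field.pixel_size))
    _, h, w = field.raster.shape
    y0, y1 = cy - half_px, cy + half_px + 1
    x0, x1 = cx - half_px, cx + half_px + 1
    if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
        raise ValueError(
            f"crop for colony at ({region.center[0]:.0f}, "
            f"{region.center[1]:.0f}) µm exceeds field bounds")
    crop = field.raster[:, y0:y1, x0:x1].copy()
    center = ((cx - x0) * field.pixel_size, (cy - y0) * field.pixel_size)
    return ColonyImage(raster=crop, center=center,
                       analysis_radius=analysis_radius,
                       pixel_size=field.pixel_size,
                       channel_names=list(field.channel_names))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_field(path, pixel_size: float, channel_names: Sequence[str]) -> FieldImage:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return FieldImage(raster=arr, pixel_size=pixel_size,
                      channel_names=list(channel_names))


def write_colony(path, colony: ColonyImage) -> None:
    tifffile.imwrite(path, colony.raster.astype(np.float32),
                     metadata={"axes": "CYX",
                               "channels": list(colony.channel_names),
                               "pixel_size_um": colony.pixel_size,
                               "center_um": list(colony.center),
                               "analysis_radius_um": colony.analysis_radius})


def write_manifest(path, regions: Sequence[ColonyRegion]) -> pd.DataFrame:
    """Colony manifest CSV: id, centre, radius, status, reason."""
    df = pd.DataFrame([
        {"colony_id": i, "center_x_um": r.center[0], "center_y_um": r.center[1],
         "radius_um": r.effective_radius, "status": r.status,
         "reason": r.reason or ""}
        for i, r in enumerate(regions)
    ])
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
    return df
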