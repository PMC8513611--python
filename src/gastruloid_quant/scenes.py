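"""Synthetic micropattern scenes with exported ground truth.

Every imaging geometry the quantification pipeline handles can be emulated
here: single 500 µm colonies, multi-colony fields (optionally exported as
overlapping tiles, optionally containing a merged colony pair), confluent
transwell-style monolayer sheets with a known number of responding nuclei
and optional ligand-secreting cells, z-stacks with a ZO-1-marked apical
surface, and reporter time-lapses.  The generators return both the raster
and a :class:`SceneTruth` sufficient to score every downstream operation.

All lengths are in µm; rasters are rendered at ``pixel_size`` µm/px
(default 1).  Nuclei are anti-aliased filled discs placed by dart throwing
with a minimum centre separation of ``min_separation_factor`` × nucleus
radius.  Noise is additive Gaussian clipped at zero.  A single
``numpy.random.default_rng(seed)`` stream drives each scene, so identical
spec + seed reproduces bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelModel",
    "Uniform",
    "CentralDisc",
    "Ring",
    "EdgeBand",
    "Mixture",
    "Suppression",
    "IntensityModel",
    "SceneSpec",
    "SceneTruth",
    "ZSceneSpec",
    "TimeSceneSpec",
    "SecretorSpec",
    "TileSet",
    "PackingError",
    "generate_colony_image",
    "generate_multicolony_field",
    "generate_zstack",
    "generate_timelapse",
    "generate_nc_timelapse",
    "generate_transwell_field",
]


class PackingError(RuntimeError):
    """Requested nucleus count cannot be placed at the minimum separation."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not place {requested} nuclei at the required separation; "
            f"achievable maximum under the attempt budget was {achieved}"
        )


# ---------------------------------------------------------------------------
# channel spatial rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelModel:
    """Base class: assigns a binary class label (0 low / 1 high) per nucleus."""

    def labels(self, radial: np.ndarray, rng: np.random.Generator,
               secretor_dist: Optional[np.ndarray] = None) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class Uniform(ChannelModel):
    """All nuclei share one class (e.g. DAPI)."""

    positive: bool = True

    def labels(self, radial, rng, secretor_dist=None):
        return np.full(radial.shape, int(self.positive), dtype=np.int8)


@dataclass(frozen=True)
class CentralDisc(ChannelModel):
    """High inside a central disc (ectoderm-like domain)."""

    radius: float

    def labels(self, radial, rng, secretor_dist=None):
        return (radial <= self.radius).astype(np.int8)


@dataclass(frozen=True)
class Ring(ChannelModel):
    """High within an annulus [r_in, r_out]."""

    r_in: float
    r_out: float

    def labels(self, radial, rng, secretor_dist=None):
        return ((radial >= self.r_in) & (radial <= self.r_out)).astype(np.int8)


@dataclass(frozen=True)
class EdgeBand(ChannelModel):
    """High within ``width`` of the colony edge (edge-restricted signaling)."""

    width: float
    colony_radius: float

    def labels(self, radial, rng, secretor_dist=None):
        return (radial >= self.colony_radius - self.width).astype(np.int8)


@dataclass(frozen=True)
class Mixture(ChannelModel):
    """A spatially random fraction of nuclei is high (salt-and-pepper)."""

    fraction_positive: float

    def __post_init__(self):
        if not 0.0 <= self.fraction_positive <= 1.0:
            raise ValueError("fraction_positive must be in [0, 1]")

    def labels(self, radial, rng, secretor_dist=None):
        n = radial.shape[0]
        k = int(round(self.fraction_positive * n))
        lab = np.zeros(n, dtype=np.int8)
        lab[rng.choice(n, size=k, replace=False)] = 1
        return lab


@dataclass(frozen=True)
class Suppression(ChannelModel):
    """Low within ``boundary`` µm of the nearest secretor cell, high beyond."""

    boundary: float

    def labels(self, radial, rng, secretor_dist=None):
        if secretor_dist is None:
            raise ValueError("Suppression model requires secretor distances")
        return (secretor_dist > self.boundary).astype(np.int8)


@dataclass(frozen=True)
class IntensityModel:
    """Per-class nuclear intensity statistics plus background and pixel noise.

    ``low``/``high`` are class means in arbitrary units; ``low_sd``/``high_sd``
    jitter the per-nucleus value; ``noise_sd`` is additive per-pixel Gaussian
    noise (clipped at 0); ``background`` is the level outside nuclei.
    """

    low: float = 0.2
    high: float = 1.0
    low_sd: float = 0.0
    high_sd: float = 0.0
    background: float = 0.05
    noise_sd: float = 0.0


# ---------------------------------------------------------------------------
# scene specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneSpec:
    """Parameterization of one synthetic colony (or sheet) scene.

    Either ``n_nuclei`` or ``density`` (nuclei/mm²) must be given.  The
    default density reproduces the live-imaging packing of 683-785 nuclei
    per 250 µm-radius colony.
    """

    pixel_size: float = 1.0
    colony_radius: float = 250.0
    n_nuclei: Optional[int] = None
    density: Optional[float] = None  # nuclei per mm^2
    nucleus_radius: float = 5.0
    channel_models: dict = field(default_factory=dict)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    channel_intensity: dict = field(default_factory=dict)  # per-channel overrides
    min_separation_factor: float = 1.6
    seed: int = 0

    def __post_init__(self):
        if self.colony_radius <= 0:
            raise ValueError("colony_radius must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_nuclei is None and self.density is None:
            raise ValueError("one of n_nuclei or density is required")

    @property
    def min_separation(self) -> float:
        return self.min_separation_factor * self.nucleus_radius

    def count_for_disc(self) -> int:
        if self.n_nuclei is not None:
            return int(self.n_nuclei)
        area_mm2 = np.pi * (self.colony_radius / 1000.0) ** 2
        return int(round(self.density * area_mm2))

    def count_for_rect(self, width: float, height: float) -> int:
        if self.n_nuclei is not None:
            return int(self.n_nuclei)
        return int(round(self.density * (width / 1000.0) * (height / 1000.0)))

    def intensity_for(self, channel: str) -> IntensityModel:
        return self.channel_intensity.get(channel, self.intensity)

    def channels(self) -> dict:
        """Channel models with DAPI guaranteed first."""
        out = {}
        if "DAPI" not in self.channel_models:
            out["DAPI"] = Uniform(positive=True)
        out.update(self.channel_models)
        return out


@dataclass(frozen=True)
class ZSceneSpec:
    """Geometry of an apical-surface z-stack (transwell monolayer style)."""

    z_planes: int = 21
    z_step: float = 1.0                     # µm between planes
    lateral_size: float = 100.0             # µm, square field
    base_height: float = 10.0               # µm, mean apical height
    undulation_amplitude: float = 0.0       # µm
    undulation_wavelength: float = 50.0     # µm
    surface_sigma_z: float = 1.0            # µm, axial extent of the ZO-1 band
    channel_offsets: dict = field(default_factory=dict)
    # per-channel (mean, sd) signed offset in µm; positive = basal (deeper z)
    gap_patches: tuple = ()                 # ((x0, y0, x1, y1), ...) ZO-1 absent

    def __post_init__(self):
        zmax = (self.z_planes - 1) * self.z_step
        lo_off = [0.0] + [m - 3 * s for m, s in self.channel_offsets.values()]
        hi_off = [0.0] + [m + 3 * s for m, s in self.channel_offsets.values()]
        lo = self.base_height - self.undulation_amplitude + min(lo_off)
        hi = self.base_height + self.undulation_amplitude + max(hi_off)
        if lo < 0 or hi > zmax:
            raise ValueError("z extent does not cover apical surface ± max offset")


@dataclass(frozen=True)
class TimeSceneSpec:
    """Time-lapse geometry: reporter-positive disc radius per frame."""

    n_frames: int = 101
    frame_interval: float = 30.0            # minutes
    radius_schedule: tuple = ()             # µm per frame
    jitter_um: float = 0.0                  # per-frame nucleus jitter (tracking)

    def __post_init__(self):
        if self.radius_schedule and len(self.radius_schedule) != self.n_frames:
            raise ValueError("radius_schedule length must equal n_frames")

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval / 60.0


@dataclass(frozen=True)
class SecretorSpec:
    """A cluster of ligand-secreting nuclei and their suppression zone."""

    n_secretors: int = 3
    cluster_center: tuple = (0.0, 0.0)      # µm, relative to scene centre
    cluster_radius: float = 10.0            # µm
    suppression_radius: float = 200.0       # µm from nearest secretor
    channel: str = "SECRETOR"


@dataclass
class SceneTruth:
    """Ground truth exported with every generated scene."""

    nuclei: pd.DataFrame                    # x_um, y_um, radial_um, label_<ch>...
    pixel_size: float
    center_um: tuple = (0.0, 0.0)           # colony centre in raster coords
    colony_radius: float = 0.0
    domain_radii: dict = field(default_factory=dict)
    colony_centers: list = field(default_factory=list)
    merged_pair: Optional[tuple] = None
    secretor_ids: list = field(default_factory=list)
    apical_surface: Optional[np.ndarray] = None
    gap_mask: Optional[np.ndarray] = None
    channel_offsets: dict = field(default_factory=dict)
    radius_schedule: Optional[np.ndarray] = None
    times_h: Optional[np.ndarray] = None
    params: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.nuclei.to_csv(outdir / "truth_nuclei.csv", index=False)
        params = dict(self.params)
        params.update(
            pixel_size=self.pixel_size,
            center_um=list(self.center_um),
            colony_radius=self.colony_radius,
            domain_radii=self.domain_radii,
            secretor_ids=list(self.secretor_ids),
        )
        def _np(o):
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        (outdir / "truth_params.json").write_text(
            json.dumps(params, indent=2, default=_np))


@dataclass
class TileSet:
    """Overlapping image tiles with explicit grid offsets (px)."""

    tiles: list                             # (row, col, y0_px, x0_px, array CxHxW)
    grid_shape: tuple
    overlap: float
    field_shape: tuple                      # (C, H, W) of the reassembled field
    pixel_size: float
    channel_names: list


# ---------------------------------------------------------------------------
# placement and rendering primitives
# ---------------------------------------------------------------------------


def _dart_throw_disc(rng, n: int, radius: float, min_sep: float,
                     center=(0.0, 0.0)) -> np.ndarray:
    """Place ``n`` points in a disc with pairwise separation ≥ min_sep."""
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 10 * max(n, 1)
    sep2 = min_sep ** 2
    while placed < n and attempts < max_attempts:
        attempts += 1
        r = radius * np.sqrt(rng.random())
        th = 2 * np.pi * rng.random()
        p = np.array([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])
        if placed:
            d2 = np.sum((pts[:placed] - p) ** 2, axis=1)
            if d2.min() < sep2:
                continue
        pts[placed] = p
        placed += 1
    if placed < n:
        raise PackingError(n, placed)
    return pts


def _dart_throw_rect(rng, n: int, width: float, height: float,
                     min_sep: float) -> np.ndarray:
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 10 * max(n, 1)
    sep2 = min_sep ** 2
    while placed < n and attempts < max_attempts:
        attempts += 1
        p = rng.random(2) * (width, height)
        if placed:
            d2 = np.sum((pts[:placed] - p) ** 2, axis=1)
            if d2.min() < sep2:
                continue
        pts[placed] = p
        placed += 1
    if placed < n:
        raise PackingError(n, placed)
    return pts


def _render_discs(img: np.ndarray, centers_px: np.ndarray, radius_px: float,
                  values: np.ndarray) -> None:
    """Alpha-composite anti-aliased discs onto ``img`` (in place)."""
    h, w = img.shape
    r = radius_px
    pad = int(np.ceil(r)) + 1
    for (cx, cy), v in zip(centers_px, values):
        x0, x1 = int(np.floor(cx)) - pad, int(np.floor(cx)) + pad + 1
        y0, y1 = int(np.floor(cy)) - pad, int(np.floor(cy)) + pad + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        ys = np.arange(y0c, y1c)[:, None]
        xs = np.arange(x0c, x1c)[None, :]
        dist = np.hypot(xs - cx, ys - cy)
        cov = np.clip(r + 0.5 - dist, 0.0, 1.0)
        patch = img[y0c:y1c, x0c:x1c]
        patch *= 1.0 - cov
        patch += cov * v


def _class_values(rng, labels: np.ndarray, im: IntensityModel) -> np.ndarray:
    """Per-nucleus rendered value for one channel given class labels."""
    means = np.where(labels == 1, im.high, im.low)
    sds = np.where(labels == 1, im.high_sd, im.low_sd)
    vals = means + rng.standard_normal(labels.shape) * sds
    return np.clip(vals, 0.0, None)


def _add_noise(rng, raster: np.ndarray, sd: float) -> np.ndarray:
    if sd > 0:
        raster = raster + rng.standard_normal(raster.shape) * sd
    return np.clip(raster, 0.0, None)


def _render_scene(rng, spec: SceneSpec, centers_um: np.ndarray,
                  labels: dict, shape_px: tuple,
                  extra_noise: bool = True) -> np.ndarray:
    """Render all channels for one set of nuclei; returns (C, H, W)."""
    channels = list(labels)
    out = np.empty((len(channels), *shape_px), dtype=np.float32)
    centers_px = centers_um / spec.pixel_size
    r_px = spec.nucleus_radius / spec.pixel_size
    for ci, ch in enumerate(channels):
        im = spec.intensity_for(ch)
        img = np.full(shape_px, im.background, dtype=np.float64)
        vals = _class_values(rng, labels[ch], im)
        _render_discs(img, centers_px, r_px, vals)
        if extra_noise:
            img = _add_noise(rng, img, im.noise_sd)
        out[ci] = img
    return out


def _truth_frame(centers_um, center, labels: dict) -> pd.DataFrame:
    radial = np.hypot(centers_um[:, 0] - center[0], centers_um[:, 1] - center[1])
    df = pd.DataFrame({
        "nucleus_id": np.arange(len(centers_um)),
        "x_um": centers_um[:, 0],
        "y_um": centers_um[:, 1],
        "radial_um": radial,
    })
    for ch, lab in labels.items():
        df[f"label_{ch}"] = lab
    return df


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_colony_image(spec: SceneSpec):
    """Render one circular colony; returns (ColonyImage, SceneTruth)."""
    from .colony import ColonyImage  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed)
    n = spec.count_for_disc()
    margin = 2.0 * spec.nucleus_radius
    half_um = spec.colony_radius + margin
    side = int(np.ceil(2 * half_um / spec.pixel_size)) | 1  # odd: exact centre px
    center = ((side - 1) / 2.0 * spec.pixel_size,) * 2

    place_r = spec.colony_radius - spec.nucleus_radius
    centers = _dart_throw_disc(rng, n, place_r, spec.min_separation, center)
    radial = np.hypot(centers[:, 0] - center[0], centers[:, 1] - center[1])

    labels = {ch: m.labels(radial, rng) for ch, m in spec.channels().items()}
    raster = _render_scene(rng, spec, centers, labels, (side, side))

    truth = SceneTruth(
        nuclei=_truth_frame(centers, center, labels),
        pixel_size=spec.pixel_size,
        center_um=center,
        colony_radius=spec.colony_radius,
        params={"seed": spec.seed, "n_nuclei": n},
    )
    colony = ColonyImage(
        raster=raster,
        center=center,
        analysis_radius=spec.colony_radius,
        pixel_size=spec.pixel_size,
        channel_names=list(labels),
    )
    return colony, truth


def generate_multicolony_field(spec: SceneSpec, layout: Sequence[tuple],
                               include_merged: bool = False,
                               field_size: Optional[tuple] = None,
                               tile_grid: Optional[tuple] = None,
                               tile_overlap: float = 0.1):
    """Render a field of colonies at ``layout`` centres (µm).

    With ``include_merged`` one extra colony is placed 1.5 radii from the
    first layout centre, producing exactly one merged pair.  With
    ``tile_grid=(rows, cols)`` the field is additionally cut into
    overlapping tiles (returned as a :class:`TileSet` in place of the
    field raster).
    """
    from .colony import FieldImage

    rng = np.random.default_rng(spec.seed)
    layout = [tuple(c) for c in layout]
    merged_pair = None
    if include_merged:
        # partner 1.5 radii from the first colony, in a direction that keeps
        # it well clear of every other colony (2.5 radii: footprint closure
        # during detection can bridge gaps of order the closure scale)
        extra = None
        for require_bounds in (True, False):
            for ang in np.linspace(0.0, 2 * np.pi, 24, endpoint=False):
                cand = (layout[0][0] + 1.5 * spec.colony_radius * np.cos(ang),
                        layout[0][1] + 1.5 * spec.colony_radius * np.sin(ang))
                clear = all(np.hypot(cand[0] - c[0], cand[1] - c[1])
                            >= 2.5 * spec.colony_radius for c in layout[1:])
                if clear and (min(cand) >= spec.colony_radius
                              or not require_bounds):
                    extra = cand
                    break
            if extra is not None:
                break
        if extra is None:
            raise ValueError("no room to place a merged partner colony")
        merged_pair = (0, len(layout))
        layout = layout + [extra]
    else:
        for i in range(len(layout)):
            for j in range(i + 1, len(layout)):
                d = np.hypot(layout[i][0] - layout[j][0],
                             layout[i][1] - layout[j][1])
                if d < 2 * spec.colony_radius:
                    raise ValueError(
                        f"colonies {i} and {j} overlap (centre distance "
                        f"{d:.1f} µm < {2 * spec.colony_radius:.1f} µm) "
                        "but include_merged is False"
                    )

    if field_size is None:
        pad = spec.colony_radius + 4 * spec.nucleus_radius
        xs = [c[0] for c in layout]
        ys = [c[1] for c in layout]
        field_size = (max(xs) + pad, max(ys) + pad)
    w_px = int(np.ceil(field_size[0] / spec.pixel_size))
    h_px = int(np.ceil(field_size[1] / spec.pixel_size))

    n_per = spec.count_for_disc()
    place_r = spec.colony_radius - spec.nucleus_radius
    all_centers, all_labels, frames = [], [], []
    channel_names = list(spec.channels())
    for ci, c in enumerate(layout):
        centers = _dart_throw_disc(rng, n_per, place_r, spec.min_separation, c)
        radial = np.hypot(centers[:, 0] - c[0], centers[:, 1] - c[1])
        labels = {ch: m.labels(radial, rng) for ch, m in spec.channels().items()}
        df = _truth_frame(centers, c, labels)
        df.insert(0, "colony_id", ci)
        frames.append(df)
        all_centers.append(centers)
        all_labels.append(labels)

    centers_cat = np.concatenate(all_centers)
    labels_cat = {ch: np.concatenate([lab[ch] for lab in all_labels])
                  for ch in channel_names}
    raster = _render_scene(rng, spec, centers_cat, labels_cat, (h_px, w_px))

    truth = SceneTruth(
        nuclei=pd.concat(frames, ignore_index=True),
        pixel_size=spec.pixel_size,
        colony_radius=spec.colony_radius,
        colony_centers=layout,
        merged_pair=merged_pair,
        params={"seed": spec.seed, "field_size": list(field_size)},
    )

    if tile_grid is not None:
        tiles = _cut_tiles(raster, tile_grid, tile_overlap)
        ts = TileSet(tiles=tiles, grid_shape=tile_grid, overlap=tile_overlap,
                     field_shape=raster.shape, pixel_size=spec.pixel_size,
                     channel_names=channel_names)
        return ts, truth

    fld = FieldImage(raster=raster, pixel_size=spec.pixel_size,
                     channel_names=channel_names)
    return fld, truth


def _cut_tiles(raster: np.ndarray, grid: tuple, overlap: float) -> list:
    rows, cols = grid
    _, h, w = raster.shape
    th = int(np.ceil(h / (rows - (rows - 1) * overlap))) if rows > 1 else h
    tw = int(np.ceil(w / (cols - (cols - 1) * overlap))) if cols > 1 else w
    step_y = int(round(th * (1 - overlap)))
    step_x = int(round(tw * (1 - overlap)))
    tiles = []
    for r in range(rows):
        for c in range(cols):
            y0 = min(r * step_y, h - th)
            x0 = min(c * step_x, w - tw)
            tiles.append((r, c, y0, x0, raster[:, y0:y0 + th, x0:x0 + tw].copy()))
    return tiles


def generate_transwell_field(spec: SceneSpec, n_positive: Optional[int] = None,
                             response_channel: str = "RESPONSE",
                             secretors: Optional[SecretorSpec] = None,
                             layout: str = "sheet"):
    """Render a monolayer scene with a controlled number of responding nuclei.

    ``layout='sheet'`` fills a square field (transwell filter);
    ``layout='disc'`` fills the colony disc (used for secretor scenes).
    When ``secretors`` is given, secretor nuclei are placed inside the
    specified cluster, marked in a dedicated channel, and the response
    channel is suppressed for every non-secretor nucleus within
    ``suppression_radius`` of its nearest secretor.
    """
    from .colony import ColonyImage

    rng = np.random.default_rng(spec.seed)
    margin = 2.0 * spec.nucleus_radius
    if layout == "disc":
        half_um = spec.colony_radius + margin
        side = int(np.ceil(2 * half_um / spec.pixel_size)) | 1
        shape_px = (side, side)
        center = ((side - 1) / 2.0 * spec.pixel_size,) * 2
        n = spec.count_for_disc()
    elif layout == "sheet":
        width = 2 * spec.colony_radius
        side = int(np.ceil(width / spec.pixel_size)) | 1
        shape_px = (side, side)
        center = ((side - 1) / 2.0 * spec.pixel_size,) * 2
        n = spec.count_for_rect(width, width)
    else:
        raise ValueError("layout must be 'sheet' or 'disc'")

    secretor_centers = np.empty((0, 2))
    n_secr = 0
    if secretors is not None:
        n_secr = secretors.n_secretors
        sc = (center[0] + secretors.cluster_center[0],
              center[1] + secretors.cluster_center[1])
        secretor_centers = _dart_throw_disc(
            rng, n_secr, secretors.cluster_radius, spec.min_separation, sc)

    n_rest = n - n_secr
    if n_rest < 0:
        raise ValueError("more secretors than nuclei")
    # rejection against secretors keeps the global minimum separation
    rest = []
    attempts = 0
    max_attempts = 10 * max(n_rest, 1)
    sep2 = spec.min_separation ** 2
    while len(rest) < n_rest and attempts < max_attempts:
        attempts += 1
        if layout == "disc":
            r = (spec.colony_radius - spec.nucleus_radius) * np.sqrt(rng.random())
            th = 2 * np.pi * rng.random()
            p = np.array([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])
        else:
            pad = spec.nucleus_radius
            p = pad + rng.random(2) * (side * spec.pixel_size - 2 * pad)
        prev = np.array(rest) if rest else np.empty((0, 2))
        cand = np.concatenate([secretor_centers, prev])
        if cand.size and np.sum((cand - p) ** 2, axis=1).min() < sep2:
            continue
        rest.append(p)
    if len(rest) < n_rest:
        raise PackingError(n_rest, len(rest))

    centers = np.concatenate([secretor_centers, np.array(rest).reshape(-1, 2)])
    radial = np.hypot(centers[:, 0] - center[0], centers[:, 1] - center[1])
    is_secretor = np.zeros(n, dtype=bool)
    is_secretor[:n_secr] = True

    labels = {"DAPI": np.ones(n, dtype=np.int8)}
    if secretors is not None:
        labels[secretors.channel] = is_secretor.astype(np.int8)
        d = np.hypot(centers[:, None, 0] - secretor_centers[None, :, 0],
                     centers[:, None, 1] - secretor_centers[None, :, 1])
        nearest = d.min(axis=1)
        resp = (nearest > secretors.suppression_radius).astype(np.int8)
        resp[is_secretor] = 0
        labels[response_channel] = resp
    else:
        if n_positive is None:
            raise ValueError("n_positive is required without secretors")
        if n_positive > n:
            raise ValueError("n_positive exceeds nucleus count")
        lab = np.zeros(n, dtype=np.int8)
        lab[rng.choice(n, size=n_positive, replace=False)] = 1
        labels[response_channel] = lab

    raster = _render_scene(rng, spec, centers, labels, shape_px)
    truth_df = _truth_frame(centers, center, labels)
    truth_df["is_secretor"] = is_secretor
    truth = SceneTruth(
        nuclei=truth_df,
        pixel_size=spec.pixel_size,
        center_um=center,
        colony_radius=spec.colony_radius,
        secretor_ids=list(np.where(is_secretor)[0]),
        params={"seed": spec.seed, "layout": layout,
                "n_positive": n_positive},
    )
    img = ColonyImage(raster=raster, center=center,
                      analysis_radius=spec.colony_radius,
                      pixel_size=spec.pixel_size,
                      channel_names=list(labels))
    return img, truth


def generate_zstack(zspec: ZSceneSpec, spec: SceneSpec):
    """Render a multi-channel z-stack around a ZO-1 apical surface.

    Returns ``(stack, channel_names, truth)`` where ``stack`` has axes
    (C, Z, Y, X).  The ZO-1 channel is a Gaussian band in z centred on the
    analytic surface; each other channel is offset by its sampled signed
    distance (positive = basal, i.e. deeper z).
    """
    rng = np.random.default_rng(spec.seed)
    npx = int(np.ceil(zspec.lateral_size / spec.pixel_size))
    zs = np.arange(zspec.z_planes) * zspec.z_step
    xs = np.arange(npx) * spec.pixel_size
    ys = np.arange(npx) * spec.pixel_size
    X, Y = np.meshgrid(xs, ys)

    surface = (zspec.base_height
               + zspec.undulation_amplitude
               * np.sin(2 * np.pi * X / zspec.undulation_wavelength)
               * np.cos(2 * np.pi * Y / zspec.undulation_wavelength))

    gap_mask = np.zeros((npx, npx), dtype=bool)
    for (x0, y0, x1, y1) in zspec.gap_patches:
        gap_mask |= (X >= x0) & (X < x1) & (Y >= y0) & (Y < y1)

    im = spec.intensity
    channel_names = ["ZO1"] + list(zspec.channel_offsets)
    stack = np.empty((len(channel_names), zspec.z_planes, npx, npx),
                     dtype=np.float32)
    offsets_truth = {}
    sig = zspec.surface_sigma_z
    for ci, ch in enumerate(channel_names):
        if ch == "ZO1":
            depth = surface
            amp = np.where(gap_mask, 0.0, im.high)
        else:
            mu, sd = zspec.channel_offsets[ch]
            off = mu + sd * rng.standard_normal(surface.shape)
            offsets_truth[ch] = off
            depth = surface + off
            amp = np.full(surface.shape, im.high)
        prof = amp[None] * np.exp(-0.5 * ((zs[:, None, None] - depth[None]) / sig) ** 2)
        vol = im.background + prof
        if im.noise_sd > 0:
            vol = vol + rng.standard_normal(vol.shape) * im.noise_sd
        stack[ci] = np.clip(vol, 0.0, None)

    truth = SceneTruth(
        nuclei=pd.DataFrame(),
        pixel_size=spec.pixel_size,
        apical_surface=surface,
        gap_mask=gap_mask,
        channel_offsets=offsets_truth,
        params={"seed": spec.seed, "z_step": zspec.z_step,
                "z_planes": zspec.z_planes},
    )
    return stack, channel_names, truth


def _timelapse_base(rng, spec: SceneSpec):
    margin = 2.0 * spec.nucleus_radius
    half_um = spec.colony_radius + margin
    side = int(np.ceil(2 * half_um / spec.pixel_size)) | 1
    center = ((side - 1) / 2.0 * spec.pixel_size,) * 2
    n = spec.count_for_disc()
    centers = _dart_throw_disc(rng, n, spec.colony_radius - spec.nucleus_radius,
                               spec.min_separation, center)
    return side, center, centers


def generate_timelapse(tspec: TimeSceneSpec, spec: SceneSpec):
    """Reporter time-lapse: a positive disc follows ``radius_schedule``.

    Returns ``(frames, channel_names, truth)``; frames have axes
    (T, C, Y, X) with channels [H2B, REPORTER].  Nucleus placements are
    shared across frames (plus optional jitter for tracking tests).
    """
    rng = np.random.default_rng(spec.seed)
    side, center, centers = _timelapse_base(rng, spec)
    schedule = np.asarray(tspec.radius_schedule, dtype=float)
    if schedule.size == 0:
        schedule = np.full(tspec.n_frames, spec.colony_radius)
    if np.any(schedule < 0) or np.any(schedule > spec.colony_radius):
        raise ValueError("radius_schedule values must lie in [0, colony_radius]")

    frames = np.empty((tspec.n_frames, 2, side, side), dtype=np.float32)
    for t in range(tspec.n_frames):
        pos = centers
        if tspec.jitter_um > 0:
            pos = centers + rng.standard_normal(centers.shape) * tspec.jitter_um
        radial = np.hypot(pos[:, 0] - center[0], pos[:, 1] - center[1])
        labels = {
            "H2B": np.ones(len(pos), dtype=np.int8),
            "REPORTER": (radial <= schedule[t]).astype(np.int8),
        }
        frames[t] = _render_scene(rng, spec, pos, labels, (side, side))

    truth = SceneTruth(
        nuclei=_truth_frame(centers, center,
                            {"H2B": np.ones(len(centers), dtype=np.int8)}),
        pixel_size=spec.pixel_size,
        center_um=center,
        colony_radius=spec.colony_radius,
        radius_schedule=schedule,
        times_h=tspec.times_h,
        params={"seed": spec.seed, "frame_interval_min": tspec.frame_interval},
    )
    return frames, ["H2B", "REPORTER"], truth


def generate_nc_timelapse(tspec: TimeSceneSpec, spec: SceneSpec,
                          nuclear_schedule: Sequence[float],
                          cyto_level: float = 1.0):
    """Reporter time-lapse for nuclear/cytoplasmic ratio analysis.

    The reporter channel is ``cyto_level`` everywhere (cytoplasm) with
    nuclei rendered at ``nuclear_schedule[t]``; the H2B channel marks
    nuclei for segmentation.  N:C truth per frame is
    ``nuclear_schedule[t] / cyto_level``.
    """
    nuclear_schedule = np.asarray(nuclear_schedule, dtype=float)
    if nuclear_schedule.size != tspec.n_frames:
        raise ValueError("nuclear_schedule length must equal n_frames")
    rng = np.random.default_rng(spec.seed)
    side, center, centers = _timelapse_base(rng, spec)
    im = spec.intensity
    centers_px = centers / spec.pixel_size
    r_px = spec.nucleus_radius / spec.pixel_size

    frames = np.empty((tspec.n_frames, 2, side, side), dtype=np.float32)
    for t in range(tspec.n_frames):
        pos_px = centers_px
        if tspec.jitter_um > 0:
            pos_px = centers_px + (rng.standard_normal(centers.shape)
                                   * tspec.jitter_um / spec.pixel_size)
        h2b = np.full((side, side), im.background, dtype=np.float64)
        _render_discs(h2b, pos_px, r_px, np.full(len(centers), im.high))
        rep = np.full((side, side), cyto_level, dtype=np.float64)
        _render_discs(rep, pos_px, r_px,
                      np.full(len(centers), nuclear_schedule[t]))
        frames[t, 0] = _add_noise(rng, h2b, im.noise_sd)
        frames[t, 1] = _add_noise(rng, rep, im.noise_sd)

    truth = SceneTruth(
        nuclei=_truth_frame(centers, center,
                            {"H2B": np.ones(len(centers), dtype=np.int8)}),
        pixel_size=spec.pixel_size,
        center_um=center,
        colony_radius=spec.colony_radius,
        radius_schedule=nuclear_schedule / cyto_level,
        times_h=tspec.times_h,
        params={"seed": spec.seed, "cyto_level": cyto_level},
    )
    return frames, ["H2B", "REPORTER"], truth


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------


def save_scene(outdir, raster: np.ndarray, truth: SceneTruth,
               channel_names: Sequence[str]) -> None:
    """Write a scene as TIFF (raster) + CSV/JSON (truth)."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "scene.tif", np.asarray(raster, dtype=np.float32),
                     metadata={"axes": "CYX" if raster.ndim == 3 else "TCYX",
                               "channels": list(channel_names)})
    truth.save(outdir)


def spec_to_json(spec) -> str:
    """Serialize a (nested) scene spec dataclass to JSON."""

    def enc(o):
        if dataclasses.is_dataclass(o):
            d = dataclasses.asdict(o)
            d["__type__"] = type(o).__name__
            return d
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    return json.dumps(spec, default=enc, indent=2)
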