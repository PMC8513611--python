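"""Time-lapse quantification: reporter-domain radius traces and SMAD N:C ratios.

Two live-imaging readouts are covered.  (1) The radius of the
reporter-positive domain (e.g. mCitrine-SOX2) over a 50 h, 30 min-interval
course: each max-projected frame is thresholded with Otsu, the binary mask
is radially profiled at pixel level, and the domain radius is the
outermost half-max crossing of that occupancy profile.  (2) Single-cell
nuclear-to-cytoplasmic (N:C) ratios of SMAD reporters: nuclei are
segmented from the H2B channel, the nuclear mean is taken over a 1 px
eroded mask, the cytoplasmic mean over a 2 px ring outside the nucleus
excluding all other nuclei, and cells are tracked across frames by
nearest-centroid linking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import expand_labels

from .nuclei import find_nucleus_seeds, segment_nuclei
from .quant import radial_profile

__all__ = [
    "RadiusTrace",
    "max_project",
    "sox2_radius_trace",
    "nc_ratio_trace",
    "summarize_cohort",
]

log = logging.getLogger(__name__)


@dataclass
class RadiusTrace:
    """Reporter-positive domain radius per frame."""

    time_h: np.ndarray
    radius_um: np.ndarray
    flags: list                  # "ok" | "no foreground" per frame
    frame_interval_min: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.time_h,
                             "radius_um": self.radius_um,
                             "flag": self.flags})


def max_project(frames: np.ndarray, z_axis: int = 1) -> np.ndarray:
    """Per-frame maximum-intensity projection over z.

    ``frames`` with axes (T, Z, Y, X) → (T, Y, X); 3D input (already
    projected) is returned unchanged.
    """
    frames = np.asarray(frames)
    if frames.ndim == 3:
        return frames
    return frames.max(axis=z_axis)


def _outermost_half_crossing(r: np.ndarray, v: np.ndarray, level: float):
    """Outermost radius where v falls through ``level`` (interpolated)."""
    above = v >= level
    if not above.any():
        return None
    last = np.nonzero(above)[0][-1]
    if last == len(v) - 1:
        return r[last]
    r0, r1 = r[last], r[last + 1]
    v0, v1 = v[last], v[last + 1]
    if v0 == v1:
        return r0
    return r0 + (v0 - level) / (v0 - v1) * (r1 - r0)


def sox2_radius_trace(series: np.ndarray, center, analysis_radius: float,
                      pixel_size: float = 1.0, frame_interval_min: float = 30.0,
                      t0_frame: int = 0, bin_width: float = 5.0) -> RadiusTrace:
    """Reporter-domain radius per frame from a (T, Y, X) series.

    Per frame: Otsu foreground mask of the reporter channel, pixel-mode
    radial profile of the mask occupancy, radius = outermost half-max
    crossing of that profile (linear interpolation).  Frames with no
    foreground get radius 0 and a flag.  Time is reported in hours from
    the declared stimulation frame ``t0_frame``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 3 or series.shape[0] < 3:
        raise ValueError("need a (T, Y, X) series with at least 3 frames")
    radii = np.zeros(series.shape[0])
    flags = []
    for t, frame in enumerate(series):
        if np.ptp(frame) == 0:
            flags.append("no foreground")
            continue
        mask = frame > threshold_otsu(frame)
        if not mask.any():
            flags.append("no foreground")
            continue
        prof = radial_profile(mask.astype(float), center=center,
                              analysis_radius=analysis_radius,
                              bin_width=bin_width, pixel_size=pixel_size)
        ok = prof.n > 0
        r, v = prof.bin_centers[ok], prof.mean[ok]
        hi = float(np.max(v))
        if hi <= 0:
            flags.append("no foreground")
            continue
        half = hi / 2.0
        edge = _outermost_half_crossing(r, v, half)
        if edge is None:
            flags.append("no foreground")
            continue
        radii[t] = min(float(edge) + bin_width / 2.0, analysis_radius)
        flags.append("ok")
    times = (np.arange(series.shape[0]) - t0_frame) * frame_interval_min / 60.0
    return RadiusTrace(time_h=times, radius_um=radii, flags=flags,
                       frame_interval_min=frame_interval_min)


# ---------------------------------------------------------------------------
# N:C ratio traces
# ---------------------------------------------------------------------------


def _frame_nc(reporter: np.ndarray, nuclear: np.ndarray, nucleus_radius: float,
              pixel_size: float, ring_px: int = 2, erosion_px: int = 1):
    """Per-nucleus centroid and N:C ratio for one frame."""
    seeds = find_nucleus_seeds(nuclear, nucleus_radius, pixel_size)
    if len(seeds) == 0:
        return pd.DataFrame(columns=["x_um", "y_um", "nc_ratio"])
    labels = segment_nuclei(nuclear, seeds, nucleus_radius, pixel_size)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return pd.DataFrame(columns=["x_um", "y_um", "nc_ratio"])

    mask = labels > 0
    eroded = labels * ndimage.binary_erosion(mask, iterations=erosion_px)
    # 1 px guard band skips the anti-aliased nuclear rim, then a
    # ring_px-wide cytoplasmic ring, excluding every other nucleus
    guard = ndimage.binary_dilation(mask, iterations=1)
    ring_assign = expand_labels(labels, distance=ring_px + 1)
    ring = np.where(guard, 0, ring_assign)

    rows = []
    coms = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
    for (cy, cx), lab in zip(coms, ids):
        nuc_px = reporter[eroded == lab]
        cyt_px = reporter[ring == lab]
        if nuc_px.size == 0 or cyt_px.size == 0:
            continue  # cytoplasmic ring empty: cell skipped this frame
        cyt = float(cyt_px.mean())
        if cyt <= 0:
            continue
        rows.append({"x_um": cx * pixel_size, "y_um": cy * pixel_size,
                     "nuclear_mean": float(nuc_px.mean()),
                     "cyto_mean": cyt,
                     "nc_ratio": float(nuc_px.mean()) / cyt})
    return pd.DataFrame(rows)


def nc_ratio_trace(reporter_frames: np.ndarray, nuclear_frames: np.ndarray,
                   nucleus_radius: float = 5.0, pixel_size: float = 1.0,
                   frame_interval_min: float = 10.0, t0_frame: int = 0,
                   max_step_um: float = 10.0) -> pd.DataFrame:
    """Single-cell N:C ratio traces from aligned reporter/H2B frame series.

    Cells are linked frame-to-frame by nearest centroid with a maximum
    step of ``max_step_um`` per frame; lost tracks are truncated (logged).
    Returns a tidy table (track_id, frame, time_h, x_um, y_um,
    nuclear_mean, cyto_mean, nc_ratio).
    """
    from scipy.spatial import cKDTree

    if reporter_frames.shape != nuclear_frames.shape:
        raise ValueError("reporter and nuclear series must be aligned")
    n_frames = reporter_frames.shape[0]

    all_rows = []
    prev_pos = None
    prev_tracks = None
    next_track = 0
    lost = 0
    for t in range(n_frames):
        df = _frame_nc(reporter_frames[t], nuclear_frames[t],
                       nucleus_radius, pixel_size)
        if df.empty:
            prev_pos, prev_tracks = None, None
            continue
        pos = df[["x_um", "y_um"]].to_numpy()
        tracks = np.full(len(df), -1, dtype=int)
        if prev_pos is not None and len(prev_pos):
            tree = cKDTree(pos)
            dist, idx = tree.query(prev_pos)
            # greedy one-to-one: closest previous cell claims each detection
            order = np.argsort(dist)
            taken = set()
            for k in order:
                if dist[k] <= max_step_um and idx[k] not in taken:
                    tracks[idx[k]] = prev_tracks[k]
                    taken.add(idx[k])
            lost += int(np.sum(dist > max_step_um))
        for k in range(len(tracks)):
            if tracks[k] < 0:
                tracks[k] = next_track
                next_track += 1
        df = df.assign(track_id=tracks, frame=t,
                       time_h=(t - t0_frame) * frame_interval_min / 60.0)
        all_rows.append(df)
        prev_pos, prev_tracks = pos, tracks
    if lost:
        log.info("truncated %d track links exceeding the maximum step", lost)
    if not all_rows:
        return pd.DataFrame(columns=["track_id", "frame", "time_h", "x_um",
                                     "y_um", "nuclear_mean", "cyto_mean",
                                     "nc_ratio"])
    out = pd.concat(all_rows, ignore_index=True)
    return out[["track_id", "frame", "time_h", "x_um", "y_um",
                "nuclear_mean", "cyto_mean", "nc_ratio"]]


def summarize_cohort(traces: pd.DataFrame,
                     value: str = "nc_ratio") -> pd.DataFrame:
    """Frame-aligned mean ± sd with n over all cells present in each frame."""
    if traces.empty:
        raise ValueError("no traces to summarize")
    g = traces.groupby("frame")[value]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1),
                        "n": g.size()}).reset_index()
    times = traces.groupby("frame")["time_h"].first()
    out["time_h"] = times.values
    return out[["frame", "time_h", "mean", "sd", "n"]]
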