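"""Alpha-shape delineation of solid footprints from scattered foreground points.

The alpha shape generalizes the convex hull: a Delaunay triangulation of
the point set is pruned to the triangles whose circumradius is at most
``alpha`` (here in µm), and the union of the surviving triangles is the
footprint.  Small alpha follows concavities tightly; large alpha tends to
the convex hull.  Used both for colony detection and for delineating solid
germ-layer domains from thresholded pixels.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

__all__ = ["alpha_shape", "polygons_of", "rasterize_polygon"]


def _circumradius(pa, pb, pc):
    # vectorized over triangles; degenerate triangles get radius = inf
    a = np.linalg.norm(pb - pc, axis=1)
    b = np.linalg.norm(pa - pc, axis=1)
    c = np.linalg.norm(pa - pb, axis=1)
    s = (a + b + c) / 2.0
    area2 = np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None)
    area = np.sqrt(area2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (4.0 * area)
    r[~np.isfinite(r)] = np.inf
    return r


def alpha_shape(points: np.ndarray, alpha: float):
    """Alpha shape of 2D ``points`` (n, 2): union of Delaunay triangles with
    circumradius ≤ ``alpha``.  Returns a shapely Polygon or MultiPolygon
    (possibly empty for degenerate input)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        return Polygon()
    try:
        tri = Delaunay(points)
    except QhullError:
        return Polygon()
    simp = tri.simplices
    pa, pb, pc = (points[simp[:, i]] for i in range(3))
    keep = _circumradius(pa, pb, pc) <= alpha
    if not np.any(keep):
        return Polygon()
    tris = shapely.polygons(np.stack([pa[keep], pb[keep], pc[keep]], axis=1))
    return unary_union(tris)


def polygons_of(geom) -> list:
    """Individual Polygon parts of a (Multi)Polygon, largest first."""
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        parts = [geom]
    elif isinstance(geom, MultiPolygon):
        parts = list(geom.geoms)
    else:  # GeometryCollection from a degenerate union
        parts = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    return sorted(parts, key=lambda p: p.area, reverse=True)


def rasterize_polygon(poly, shape: tuple, pixel_size: float,
                      mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside ``poly``.

    Pixel centres sit at integer pixel coordinates; positions are in µm
    (x = column × pixel_size, y = row × pixel_size).  ``mask`` optionally
    restricts the pixels tested.
    """
    h, w = shape
    if poly.is_empty:
        return np.zeros(shape, dtype=bool)
    if mask is None:
        ys, xs = np.mgrid[0:h, 0:w]
        ys = ys.ravel()
        xs = xs.ravel()
    else:
        ys, xs = np.nonzero(mask)
    inside = shapely.contains_xy(poly, xs * pixel_size, ys * pixel_size)
    out = np.zeros(shape, dtype=bool)
    out[ys[inside], xs[inside]] = True
    return out
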