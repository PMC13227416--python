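"""Per-frame morphometrics of the luminal outline and closure-time registration.

The lumen is the open region between the two converging rows of cardiac
progenitors.  Each frame's outline is a simple polygon in embryo coordinates
(x = medial-lateral, y = anterior-posterior, μm).  This module measures

* area ``a`` and perimeter ``p`` of the outline,
* circularity ``c = 4*pi*a / p**2`` (1 for a circle),
* maximum AP and ML luminal lengths, obtained by rotating the outline so its
  longest axis (maximum-caliper diameter of the convex hull) is vertical and
  reading the y- and x-extents,
* the ML extent in the native embryo frame, the proxy for the distance
  between the contralateral F-actin cables,

and registers the time origin as the *last* frame at which the ML extent
exceeds the cable threshold (80 μm by default).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .datatypes import LumenSeries, RunConfig, validate_polygon
from .errors import InsufficientDataError, ValidationError

log = logging.getLogger("cardiodyn")


def polygon_area(vertices: np.ndarray) -> float:
    """Absolute (orientation-independent) area of a simple polygon, μm²."""
    verts = validate_polygon(vertices)
    return Polygon(verts).area


def polygon_perimeter(vertices: np.ndarray) -> float:
    """Closed-contour length including the closing edge, μm."""
    verts = validate_polygon(vertices)
    return Polygon(verts).length


def circularity(area: float, perimeter: float) -> float:
    """Isoperimetric circularity 4*pi*a/p**2; 1 for a circle, < 1 otherwise."""
    if perimeter <= 0:
        raise ValidationError("perimeter must be > 0")
    if area <= 0:
        raise ValidationError("area must be > 0")
    return 4.0 * math.pi * area / perimeter**2


def _caliper_direction(verts: np.ndarray) -> np.ndarray:
    """Unit vector along the maximum-caliper (diameter) axis of the hull."""
    hull = Polygon(verts).convex_hull
    if hull.geom_type != "Polygon":  # collinear input
        raise ValidationError("degenerate polygon: convex hull has no area")
    pts = np.asarray(hull.exterior.coords)[:-1]
    # O(h^2) pairwise search; hulls here have tens of vertices at most
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff**2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    v = pts[j] - pts[i]
    return v / np.linalg.norm(v)


def max_axis_lengths(vertices: np.ndarray) -> tuple[float, float]:
    """Maximum AP and ML luminal lengths, μm.

    Rotates the outline about its centroid so that the longest axis is
    vertical, then returns ``(ap_length, ml_length)`` = (y-extent, x-extent).
    The AP length equals the maximum caliper diameter, so the result is
    invariant to any rigid rotation of the input.
    """
    verts = validate_polygon(vertices)
    d = _caliper_direction(verts)
    # rotate so that d maps onto +y: R = [[d_y, -d_x], [d_x, d_y]]
    rot = np.array([[d[1], -d[0]], [d[0], d[1]]])
    centred = verts - verts.mean(axis=0)
    rv = centred @ rot.T
    ap = float(rv[:, 1].max() - rv[:, 1].min())
    ml = float(rv[:, 0].max() - rv[:, 0].min())
    return ap, ml


def ml_extent(vertices: np.ndarray) -> float:
    """x-extent of the outline in the native (unrotated) embryo frame, μm."""
    verts = validate_polygon(vertices)
    return float(verts[:, 0].max() - verts[:, 0].min())


def register_lumen_time(series: LumenSeries, cable_threshold: float = 80.0) -> int:
    """Frame index of the closure time origin.

    t0 is the last frame at which the ML extent of the outline exceeds
    ``cable_threshold``.  If no frame exceeds it, the first frame is used
    and a warning is logged.
    """
    if len(series) == 0:
        raise InsufficientDataError("empty lumen series")
    extents = np.array([ml_extent(v) for _, v in series.frames])
    above = np.nonzero(extents > cable_threshold)[0]
    if len(above) == 0:
        log.warning(
            "%s: no frame exceeds the %.4g um cable threshold; t0 set to first frame",
            series.meta.embryo_id,
            cable_threshold,
        )
        return int(series.frames[0][0])
    return int(series.frames[int(above[-1])][0])


def compute_lumen_metrics(series: LumenSeries, config: RunConfig | None = None) -> pd.DataFrame:
    """Per-frame metrics table with registered time.

    Columns: ``frame, t_min, area_um2, perimeter_um, circularity,
    ap_len_um, ml_len_um``.  ``t_min`` is ``(frame - t0) * frame_interval``
    in minutes, negative before the registration origin.
    """
    config = config or RunConfig()
    t0 = register_lumen_time(series, config.cable_threshold)
    dt_min = series.meta.frame_interval / 60.0
    rows = []
    for idx, verts in series.frames:
        try:
            a = polygon_area(verts)
            p = polygon_perimeter(verts)
            ap, ml_rot = max_axis_lengths(verts)
        except ValidationError as exc:
            raise ValidationError(f"{series.meta.embryo_id} frame {idx}: {exc}") from exc
        rows.append(
            {
                "frame": idx,
                "t_min": (idx - t0) * dt_min,
                "area_um2": a,
                "perimeter_um": p,
                "circularity": circularity(a, p),
                "ap_len_um": ap,
                "ml_len_um": ml_rot,
            }
        )
    return pd.DataFrame(rows)
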