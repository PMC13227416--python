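import numpy as np
import pytest

from cardiodyn import EmbryoMeta, LumenSeries, NucleusTrack


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def meta():
    return EmbryoMeta(embryo_id="e1", sex="female", frame_interval=15.0)


def make_rect(ml, ap, center=(0.0, 0.0)):
    """Axis-aligned rectangle with given ML (x) and AP (y) extents."""
    cx, cy = center
    return np.array(
        [
            [cx - ml / 2, cy - ap / 2],
            [cx + ml / 2, cy - ap / 2],
            [cx + ml / 2, cy + ap / 2],
            [cx - ml / 2, cy + ap / 2],
        ]
    )


def rect_series(ml_extents, meta=None, ap=10.0):
    """LumenSeries of rectangles with prescribed per-frame ML extents."""
    meta = meta or EmbryoMeta(embryo_id="rects")
    frames = [(i, make_rect(ml, ap)) for i, ml in enumerate(ml_extents)]
    return LumenSeries(meta=meta, frames=frames)


def straight_track(cb_id, row, x0, vx_um_per_hr, n_frames=20, dt=15.0, y=0.0):
    """Track moving linearly in x at a constant speed."""
    frames = np.arange(n_frames)
    t_hr = frames * dt / 3600.0
    x = x0 + vx_um_per_hr * t_hr
    return NucleusTrack(
        cardioblast_id=cb_id, row=row, frames=frames,
        xy=np.column_stack([x, np.full(n_frames, y)]),
    )


def random_convex_polygon(rng, n_points=12, scale=10.0):
    """Convex hull of random Gaussian points, as an (m, 2) vertex array."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(0.0, scale, (n_points, 2))
    hull = ConvexHull(pts)
    return pts[hull.vertices]
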