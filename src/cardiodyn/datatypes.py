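"""Shared data model.

Coordinate convention
---------------------
``x`` is the medial-lateral (ML) axis and ``y`` the anterior-posterior (AP)
axis, both in micrometres.  The origin is arbitrary per embryo; every
downstream computation uses coordinate differences only.  Frames are integer
indices; physical time is ``frame_index * frame_interval`` with the interval
in seconds (15 s for the spinning-disk movies this package was written for).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .errors import ValidationError

SEXES = ("female", "male", "unknown")
ROWS = ("left", "right")


@dataclass
class EmbryoMeta:
    """Identity and acquisition metadata for one embryo movie."""

    embryo_id: str
    sex: str = "unknown"
    frame_interval: float = 15.0  # seconds between frames
    pixel_size: float | None = None  # μm/pixel, only for pixel-space inputs

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0 when present")


def validate_polygon(vertices: np.ndarray, where: str = "polygon") -> np.ndarray:
    """Validate one closed luminal outline.

    Accepts an (n, 2) array of μm vertices; a repeated final vertex is
    deduplicated (the closing edge is always implicit).  Rejects polygons
    with fewer than three vertices, self-intersections, or zero area.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise ValidationError(f"{where}: vertices must be an (n, 2) array")
    if len(verts) > 1 and np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    if len(verts) < 3:
        raise ValidationError(f"{where}: polygon needs >= 3 vertices, got {len(verts)}")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise ValidationError(f"{where}: polygon is not simple (self-intersecting)")
    if poly.area == 0.0:
        raise ValidationError(f"{where}: degenerate (zero-area) polygon")
    return verts


@dataclass
class LumenSeries:
    """Time-indexed closed outlines of one heart lumen.

    ``frames`` maps strictly increasing integer frame indices to (n, 2)
    vertex arrays in μm.
    """

    meta: EmbryoMeta
    frames: list[tuple[int, np.ndarray]]

    def __post_init__(self) -> None:
        cleaned = []
        prev = None
        for idx, verts in self.frames:
            idx = int(idx)
            if prev is not None and idx <= prev:
                raise ValidationError(
                    f"{self.meta.embryo_id}: frame indices not strictly increasing at {idx}"
                )
            prev = idx
            cleaned.append((idx, validate_polygon(verts, where=f"frame {idx}")))
        self.frames = cleaned

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.frames], dtype=int)


@dataclass
class NucleusTrack:
    """Centroid trajectory of one cardioblast nucleus."""

    cardioblast_id: str
    row: str  # "left" or "right"
    frames: np.ndarray  # (n,) int, strictly increasing
    xy: np.ndarray  # (n, 2) μm

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise ValidationError(f"row must be one of {ROWS}, got {self.row!r}")
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.ndim != 1 or self.xy.shape != (len(self.frames), 2):
            raise ValidationError(f"track {self.cardioblast_id}: shape mismatch")
        if len(self.frames) < 2:
            raise ValidationError(
                f"track {self.cardioblast_id}: needs >= 2 samples to be analyzable"
            )
        if np.any(np.diff(self.frames) <= 0):
            raise ValidationError(
                f"track {self.cardioblast_id}: frame indices not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]


@dataclass
class EmbryoTracks:
    """All cardioblast tracks of one embryo plus a registered time origin."""

    meta: EmbryoMeta
    tracks: list[NucleusTrack]
    t0_index: int | None = None

    def by_row(self, row: str) -> list[NucleusTrack]:
        return [t for t in self.tracks if t.row == row]


@dataclass
class RunConfig:
    """Analysis-stage parameters.

    The two registration thresholds are the study's definitions (80 μm
    cable-to-cable, 65 μm nucleus-to-nucleus); the remaining fields are
    implementation knobs of this package.
    """

    cable_threshold: float = 80.0  # μm, ML-extent registration rule
    nuclei_threshold: float = 65.0  # μm, mean contralateral distance rule
    smoothing_window: int = 3  # frames, centred moving average for steps
    step_prominence: float = 0.3  # μm, minimum extremum prominence
    max_autocorr_lag_fraction: float = 0.5
    mann_whitney_exact_max_n: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cable_threshold <= 0 or self.nuclei_threshold <= 0:
            raise ValidationError("registration thresholds must be > 0")
        if not (0 < self.max_autocorr_lag_fraction <= 1):
            raise ValidationError("max_autocorr_lag_fraction must be in (0, 1]")
        if self.smoothing_window < 1:
            raise ValidationError("smoothing_window must be >= 1")
        if self.step_prominence < 0:
            raise ValidationError("step_prominence must be >= 0")
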