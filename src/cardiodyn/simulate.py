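"""Ground-truth-known synthetic data emulating the study's inputs.

Three generators and two rendering utilities:

* :func:`gen_lumen_series` — a closing heart lumen: a pre-closure plateau of
  frames whose ML extent sits above the 80 μm registration threshold,
  followed by an elliptical outline whose area decays as ``A0*exp(-k*t)``
  from the last plateau frame, with multiplicative area noise and additive
  vertex noise.
* :func:`gen_tracks` — two contralateral rows of cardioblast nuclei (52 per
  row by default) converging on the midline, either as drift plus a
  sinusoid or as a piecewise-linear ratchet of medial/lateral steps.
* :func:`gen_cohort` — a two-group study (female/male) with per-embryo
  parameters drawn around group means, plus the ground-truth table.
* :func:`render_stack` / :func:`kymograph` — Gaussian-spot renderings of
  tracks or outlines and space-time projections of a rectangular region.

Every generator is a pure function of its parameter object including the
seed.  The ratchet waveform snaps its cycle to the sampling grid (and gives
the longer half-phase to the larger step) so that sampled extrema attain the
programmed amplitudes exactly — the basis of the exact-recovery tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import EmbryoMeta, EmbryoTracks, LumenSeries, NucleusTrack
from .errors import ValidationError

log = logging.getLogger("cardiodyn")


# ---------------------------------------------------------------------------
# parameter objects


@dataclass
class LumenSimParams:
    """Closing-lumen simulation parameters (μm, hr, s)."""

    A0: float = 1000.0  # μm², area at decay onset
    k_true: float = 1.4  # hr⁻¹
    aspect_ratio: float = 2.0  # AP/ML extent during decay
    plateau_frames: int = 10  # frames held above the registration threshold
    plateau_ml: float = 85.0  # μm, ML extent during the plateau (> 80)
    n_frames: int = 250  # total frames including the plateau
    frame_interval: float = 15.0  # seconds
    vertex_count: int = 64
    vertex_noise_sd: float = 0.1  # μm
    area_noise_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.A0, self.k_true, self.aspect_ratio, self.plateau_ml) <= 0:
            raise ValidationError("lumen parameters must be positive")
        if self.plateau_ml <= 80.0:
            raise ValidationError("plateau_ml must exceed the 80 um registration threshold")
        if self.n_frames <= self.plateau_frames:
            raise ValidationError("n_frames must exceed plateau_frames")
        if self.vertex_count < 8 or self.vertex_count % 2:
            raise ValidationError("vertex_count must be an even integer >= 8")


@dataclass
class TrackSimParams:
    """Cardioblast track simulation parameters."""

    mode: str = "drift_sinusoid"  # or "ratchet"
    n_per_row: int = 52
    initial_separation: float = 75.0  # μm between the rows
    drift_speed: float = 23.0  # μm/hr (drift_sinusoid mode)
    period: float = 1.7  # minutes
    sin_amplitude: float = 1.0  # μm (drift_sinusoid mode)
    medial_step: float = 1.9  # μm per cycle (ratchet mode)
    lateral_step: float = 0.8  # μm per cycle (ratchet mode)
    position_noise_sd: float = 0.2  # μm
    n_frames: int = 241  # 60 min at 15 s
    frame_interval: float = 15.0  # seconds
    row_spacing_ap: float = 5.0  # μm between neighbouring nuclei in a row
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("drift_sinusoid", "ratchet"):
            raise ValidationError(f"unknown track mode {self.mode!r}")
        if self.n_per_row < 1:
            raise ValidationError("n_per_row must be >= 1")
        if self.initial_separation <= 0 or self.period <= 0:
            raise ValidationError("initial_separation and period must be > 0")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")


@dataclass
class GroupSimParams:
    """One group's generating parameters plus between-embryo spreads."""

    lumen: LumenSimParams
    tracks: TrackSimParams
    k_sd: float = 0.1  # hr⁻¹
    speed_sd: float = 6.7  # μm/hr
    period_sd: float = 0.8  # min
    medial_step_sd: float = 0.1  # μm
    lateral_step_sd: float = 0.1  # μm


def female_group_defaults() -> GroupSimParams:
    return GroupSimParams(
        lumen=LumenSimParams(k_true=1.4),
        tracks=TrackSimParams(drift_speed=23.0, period=1.7, medial_step=1.9, lateral_step=0.8),
        k_sd=0.1,
        speed_sd=6.7,
        period_sd=0.8,
        medial_step_sd=0.1,
        lateral_step_sd=0.1,
    )


def male_group_defaults() -> GroupSimParams:
    return GroupSimParams(
        lumen=LumenSimParams(k_true=1.2),
        tracks=TrackSimParams(drift_speed=22.4, period=1.4, medial_step=2.0, lateral_step=0.7),
        k_sd=0.1,
        speed_sd=3.3,
        period_sd=0.8,
        medial_step_sd=0.2,
        lateral_step_sd=0.1,
    )


@dataclass
class CohortSimParams:
    """Two-group study design: 7 vs 8 lumen embryos, 6 vs 6 track embryos."""

    female: GroupSimParams = field(default_factory=female_group_defaults)
    male: GroupSimParams = field(default_factory=male_group_defaults)
    n_lumen_female: int = 7
    n_lumen_male: int = 8
    n_track_female: int = 6
    n_track_male: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_lumen_female, self.n_lumen_male, self.n_track_female, self.n_track_male):
            if n < 1:
                raise ValidationError("every cohort group needs >= 1 embryo")


@dataclass
class Cohort:
    lumen_embryos: list[LumenSeries]
    track_embryos: list[EmbryoTracks]
    ground_truth: pd.DataFrame


# ---------------------------------------------------------------------------
# generators


def _ellipse_polygon(area: float, ml_extent: float | None, aspect_ratio: float | None,
                     n_vertices: int) -> np.ndarray:
    """Regularly sampled ellipse whose *polygon* area equals ``area``.

    Exactly one of ``ml_extent`` (fixes the x half-width) or ``aspect_ratio``
    (fixes AP/ML) must be given.  The inscribed n-gon of an ellipse with
    semiaxes (b, a) has area (n/2)·sin(2π/n)·a·b, so semiaxes are scaled to
    hit the target polygon area exactly.
    """
    fn = (n_vertices / 2.0) * math.sin(2.0 * math.pi / n_vertices)
    if ml_extent is not None:
        b = ml_extent / 2.0
        a = area / (fn * b)
    else:
        b = math.sqrt(area / (fn * aspect_ratio))
        a = aspect_ratio * b
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return np.column_stack([b * np.cos(theta), a * np.sin(theta)])


def gen_lumen_series(params: LumenSimParams, meta: EmbryoMeta | None = None) -> LumenSeries:
    """Generate a closing-lumen polygon series with known closure rate.

    Frames ``0 .. plateau_frames-1`` hold a wide outline (ML extent
    ``plateau_ml`` > 80 μm) at area A0; the last plateau frame is the decay
    origin t = 0.  Each subsequent frame i has noiseless area
    ``A0*exp(-k_true * i*dt)`` at fixed aspect ratio, multiplied by
    ``(1 + eps)`` with eps ~ N(0, area_noise_frac); every vertex is then
    perturbed by N(0, vertex_noise_sd) per coordinate.
    """
    rng = np.random.default_rng(params.seed)
    meta = meta or EmbryoMeta(embryo_id=f"sim_lumen_{params.seed}",
                              frame_interval=params.frame_interval)
    dt_hr = params.frame_interval / 3600.0
    frames: list[tuple[int, np.ndarray]] = []
    for j in range(params.plateau_frames):
        verts = _ellipse_polygon(params.A0, params.plateau_ml, None, params.vertex_count)
        verts = verts + rng.normal(0.0, params.vertex_noise_sd, verts.shape)
        frames.append((j, verts))
    n_decay = params.n_frames - params.plateau_frames
    ml_decay = 2.0 * math.sqrt(
        params.A0 / (params.aspect_ratio * (params.vertex_count / 2.0)
                     * math.sin(2.0 * math.pi / params.vertex_count))
    )
    if ml_decay >= 80.0:
        log.warning("decay-phase ML extent %.1f um is not below the 80 um threshold", ml_decay)
    for i in range(1, n_decay + 1):
        area = params.A0 * math.exp(-params.k_true * i * dt_hr)
        if params.area_noise_frac > 0:
            area *= max(0.05, 1.0 + rng.normal(0.0, params.area_noise_frac))
        verts = _ellipse_polygon(area, None, params.aspect_ratio, params.vertex_count)
        verts = verts + rng.normal(0.0, params.vertex_noise_sd, verts.shape)
        frames.append((params.plateau_frames - 1 + i, verts))
    return LumenSeries(meta=meta, frames=frames)


def _ratchet_displacement(params: TrackSimParams) -> np.ndarray:
    """Cumulative medial displacement of the grid-snapped ratchet waveform."""
    dt_min = params.frame_interval / 60.0
    n_cyc = max(2, round(params.period / dt_min))
    if params.medial_step >= params.lateral_step:
        n_up = math.ceil(n_cyc / 2)
    else:
        n_up = n_cyc // 2
    n_down = n_cyc - n_up
    cycle = np.concatenate([
        np.full(n_up, params.medial_step / n_up),
        np.full(n_down, -params.lateral_step / n_down),
    ])
    reps = math.ceil((params.n_frames - 1) / n_cyc)
    inc = np.tile(cycle, reps)[: params.n_frames - 1]
    return np.concatenate([[0.0], np.cumsum(inc)])


def gen_tracks(params: TrackSimParams, meta: EmbryoMeta | None = None) -> EmbryoTracks:
    """Generate two contralateral rows of oscillating, converging nuclei.

    drift_sinusoid mode: medial displacement ``v*t + B*(sin(2πt/T + φ) -
    sin(φ))`` with a per-nucleus random phase φ; ratchet mode: repeated
    linear advance of ``medial_step`` then retreat of ``lateral_step`` per
    cycle.  Rows start at x = ±initial_separation/2; nuclei are spaced
    ``row_spacing_ap`` apart along AP.  Gaussian position noise is added to
    both coordinates.
    """
    rng = np.random.default_rng(params.seed)
    meta = meta or EmbryoMeta(embryo_id=f"sim_tracks_{params.seed}",
                              frame_interval=params.frame_interval)
    frames = np.arange(params.n_frames)
    t_min = frames * params.frame_interval / 60.0
    tracks: list[NucleusTrack] = []
    for row, sign, prefix in (("left", -1.0, "L"), ("right", 1.0, "R")):
        for j in range(params.n_per_row):
            if params.mode == "drift_sinusoid":
                phase = rng.uniform(0.0, 2.0 * math.pi)
                disp = (params.drift_speed / 60.0) * t_min + params.sin_amplitude * (
                    np.sin(2.0 * math.pi * t_min / params.period + phase) - math.sin(phase)
                )
            else:
                disp = _ratchet_displacement(params)
            x = sign * (params.initial_separation / 2.0) - sign * disp
            y = np.full(params.n_frames, j * params.row_spacing_ap)
            if params.position_noise_sd > 0:
                x = x + rng.normal(0.0, params.position_noise_sd, params.n_frames)
                y = y + rng.normal(0.0, params.position_noise_sd, params.n_frames)
            tracks.append(
                NucleusTrack(
                    cardioblast_id=f"{prefix}{j:02d}",
                    row=row,
                    frames=frames.copy(),
                    xy=np.column_stack([x, y]),
                )
            )
    return EmbryoTracks(meta=meta, tracks=tracks)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    """One draw from N(mean, sd) rejected below ``lo`` (keeps parameters physical)."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lo:
            return float(v)
    return max(mean, lo * 1.01)


def gen_cohort(params: CohortSimParams) -> Cohort:
    """Generate a full two-group study with a ground-truth record.

    Per-embryo generating parameters are drawn from the group means with the
    configured between-embryo spreads (truncated to stay physical: k > 0.1
    hr⁻¹, speed > 2 μm/hr, period > 0.5 min, steps > 0.35 μm).
    """
    rng = np.random.default_rng(params.seed)
    lumen_embryos: list[LumenSeries] = []
    track_embryos: list[EmbryoTracks] = []
    truth_rows = []
    for sex, grp, n_lum, n_trk in (
        ("female", params.female, params.n_lumen_female, params.n_track_female),
        ("male", params.male, params.n_lumen_male, params.n_track_male),
    ):
        for i in range(n_lum):
            k_i = _truncated_normal(rng, grp.lumen.k_true, grp.k_sd, 0.1)
            eid = f"lum_{sex[0].upper()}{i + 1}"
            p_i = replace(grp.lumen, k_true=k_i, seed=int(rng.integers(0, 2**31 - 1)))
            meta = EmbryoMeta(embryo_id=eid, sex=sex, frame_interval=p_i.frame_interval)
            lumen_embryos.append(gen_lumen_series(p_i, meta))
            truth_rows.append({"embryo_id": eid, "sex": sex, "kind": "lumen", "k_true": k_i})
        for i in range(n_trk):
            eid = f"trk_{sex[0].upper()}{i + 1}"
            t_i = replace(
                grp.tracks,
                drift_speed=_truncated_normal(rng, grp.tracks.drift_speed, grp.speed_sd, 2.0),
                period=_truncated_normal(rng, grp.tracks.period, grp.period_sd, 0.5),
                medial_step=_truncated_normal(rng, grp.tracks.medial_step, grp.medial_step_sd, 0.35),
                lateral_step=_truncated_normal(rng, grp.tracks.lateral_step, grp.lateral_step_sd, 0.35),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            meta = EmbryoMeta(embryo_id=eid, sex=sex, frame_interval=t_i.frame_interval)
            track_embryos.append(gen_tracks(t_i, meta))
            truth_rows.append(
                {
                    "embryo_id": eid,
                    "sex": sex,
                    "kind": "tracks",
                    "drift_speed": t_i.drift_speed,
                    "period": t_i.period,
                    "medial_step": t_i.medial_step,
                    "lateral_step": t_i.lateral_step,
                }
            )
    return Cohort(
        lumen_embryos=lumen_embryos,
        track_embryos=track_embryos,
        ground_truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# rendering


def render_stack(
    obj: EmbryoTracks | LumenSeries,
    image_size: tuple[int, int] = (64, 64),
    psf_sd: float = 1.0,
    pixel_size: float = 1.0,
    origin: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render tracks (Gaussian spots at nuclei) or lumen outlines to a stack.

    ``origin`` is the μm coordinate of pixel (0, 0); when omitted it is
    chosen so the object fits with a 3-sigma margin.  Raises if any object
    falls outside the field of view.
    """
    h, w = image_size
    if isinstance(obj, EmbryoTracks):
        frame_ids = sorted({int(f) for t in obj.tracks for f in t.frames})
        points = {fid: [] for fid in frame_ids}
        for t in obj.tracks:
            for f, xy in zip(t.frames, t.xy):
                points[int(f)].append(xy)
    elif isinstance(obj, LumenSeries):
        frame_ids = [idx for idx, _ in obj.frames]
        points = {}
        for idx, verts in obj.frames:
            closed = np.vstack([verts, verts[:1]])
            pts = []
            for p0, p1 in zip(closed[:-1], closed[1:]):
                seg = np.linalg.norm(p1 - p0)
                n = max(2, int(seg / (0.5 * pixel_size)) + 1)
                frac = np.linspace(0.0, 1.0, n, endpoint=False)
                pts.append(p0 + frac[:, None] * (p1 - p0))
            points[idx] = list(np.vstack(pts))
        if not frame_ids:
            raise ValidationError("empty lumen series")
    else:
        raise ValidationError(f"cannot render object of type {type(obj).__name__}")

    all_pts = [p for plist in points.values() for p in plist]
    margin = 3.0 * psf_sd
    if origin is None:
        if all_pts:
            arr = np.array(all_pts)
            origin = (float(arr[:, 0].min() - margin), float(arr[:, 1].min() - margin))
        else:
            origin = (0.0, 0.0)
    ox, oy = origin
    sigma_px = psf_sd / pixel_size
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    stack = np.zeros((len(frame_ids), h, w), dtype=np.float32)
    for fi, fid in enumerate(frame_ids):
        for x_um, y_um in points[fid]:
            cx = (x_um - ox) / pixel_size
            cy = (y_um - oy) / pixel_size
            if not (0 <= cx < w and 0 <= cy < h):
                raise ValidationError(
                    f"object at ({x_um:.1f}, {y_um:.1f}) um falls outside the field of view"
                )
            stack[fi] += np.exp(-((cols - cx) ** 2 + (rows - cy) ** 2) / (2.0 * sigma_px**2))
    return stack


def kymograph(
    stack: np.ndarray,
    rect: tuple[int, int, int, int],
    axis: str = "horizontal",
) -> np.ndarray:
    """Space-time image of a rectangular region.

    Each frame's rect is projected by maximum intensity across the dimension
    perpendicular to ``axis``; the resulting 1-D profiles are stacked over
    time.  Returns a (space, time) array.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValidationError("stack must be 3-D (frames, height, width)")
    x0, y0, rw, rh = rect
    _, h, w = stack.shape
    if rw < 1 or rh < 1 or x0 < 0 or y0 < 0 or x0 + rw > w or y0 + rh > h:
        raise ValidationError(f"rect {rect} out of bounds for {w}x{h} frames")
    sub = stack[:, y0 : y0 + rh, x0 : x0 + rw]
    if axis == "horizontal":
        profiles = sub.max(axis=1)  # (time, rw)
    elif axis == "vertical":
        profiles = sub.max(axis=2)  # (time, rh)
    else:
        raise ValidationError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    return profiles.T
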