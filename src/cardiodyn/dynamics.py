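"""Cardioblast migration metrics from nuclear centroid tracks.

Cardioblasts migrate toward the dorsal midline in two contralateral rows,
advancing through cyclic forward (medial) and backward (lateral) steps
superimposed on a net drift.  From per-nucleus centroid tracks this module
computes:

* contralateral pairing by AP rank and the per-frame pair-distance series,
* the registration origin (last frame with mean pair distance above the
  65 μm threshold),
* migration speed — the least-squares slope of distance travelled
  (displacement from the track start) versus time, μm/hr,
* the oscillation period — the lag of the first significant peak of the
  autocorrelation of the medial velocity, refined by parabolic
  interpolation, minutes,
* step decomposition — mean medial and lateral excursion amplitudes between
  alternating extrema of the medial position, and their difference, the net
  medial step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import EmbryoTracks, NucleusTrack, RunConfig
from .errors import InsufficientDataError, ValidationError

log = logging.getLogger("cardiodyn")


@dataclass
class PairedDistanceSeries:
    """Per-frame contralateral nucleus-to-nucleus distances.

    ``mean_distance[i]`` is the across-pair mean at ``frames[i]``;
    ``per_pair`` has one row per frame and one column per pair (NaN where a
    member is missing from that frame).
    """

    frames: np.ndarray
    mean_distance: np.ndarray
    per_pair: pd.DataFrame


@dataclass
class StepDecomposition:
    medial_amp: float  # μm, mean min->max excursion (NaN if no steps at all)
    lateral_amp: float  # μm, mean max->min excursion
    net_medial_step: float  # μm, medial_amp - lateral_amp
    n_medial_steps: int
    n_lateral_steps: int


@dataclass
class OscillationMetrics:
    cardioblast_id: str
    speed: float  # μm/hr
    period: float  # minutes, NaN when no qualifying autocorrelation peak
    medial_amp: float
    lateral_amp: float
    net_medial_step: float
    n_medial_steps: int
    n_lateral_steps: int


def pair_contralateral(tracks: EmbryoTracks) -> list[tuple[str, str]]:
    """Pair left- and right-row tracks by anterior-posterior rank.

    Rows are ordered collectives with preserved neighbour relationships, so
    the i-th track of each row sorted by mean AP position are paired.
    Surplus tracks on the longer side are left unpaired and logged.
    """
    left = tracks.by_row("left")
    right = tracks.by_row("right")
    if not left or not right:
        raise ValidationError("pairing requires at least one track per row")
    left.sort(key=lambda t: float(t.y.mean()))
    right.sort(key=lambda t: float(t.y.mean()))
    n = min(len(left), len(right))
    if len(left) != len(right):
        surplus = [t.cardioblast_id for t in (left if len(left) > n else right)[n:]]
        log.info("%d unpaired track(s): %s", len(surplus), ", ".join(surplus))
    return [(left[i].cardioblast_id, right[i].cardioblast_id) for i in range(n)]


def contralateral_distance(
    tracks: EmbryoTracks, pairs: list[tuple[str, str]]
) -> PairedDistanceSeries:
    """Per-frame Euclidean distance for each pair and the across-pair mean."""
    by_id = {t.cardioblast_id: t for t in tracks.tracks}
    cols = {}
    for lid, rid in pairs:
        lt, rt = by_id[lid], by_id[rid]
        common, li, ri = np.intersect1d(lt.frames, rt.frames, return_indices=True)
        if len(common) == 0:
            raise ValidationError(f"pair ({lid}, {rid}) shares no common frame")
        d = np.linalg.norm(lt.xy[li] - rt.xy[ri], axis=1)
        cols[f"{lid}|{rid}"] = pd.Series(d, index=common)
    per_pair = pd.DataFrame(cols)
    per_pair.index.name = "frame"
    per_pair = per_pair.sort_index()
    mean = per_pair.mean(axis=1, skipna=True)
    return PairedDistanceSeries(
        frames=per_pair.index.to_numpy(),
        mean_distance=mean.to_numpy(),
        per_pair=per_pair,
    )


def register_tracks_time(series: PairedDistanceSeries, nuclei_threshold: float = 65.0) -> int:
    """Last frame with mean contralateral distance above the threshold."""
    if len(series.frames) == 0:
        raise InsufficientDataError("empty distance series")
    above = np.nonzero(series.mean_distance > nuclei_threshold)[0]
    if len(above) == 0:
        log.warning(
            "no frame exceeds the %.4g um nuclei threshold; t0 set to first frame",
            nuclei_threshold,
        )
        return int(series.frames[0])
    return int(series.frames[int(above[-1])])


def migration_speed(track: NucleusTrack, frame_interval: float = 15.0) -> float:
    """Slope of distance travelled versus time, μm/hr.

    Distance travelled is the displacement from the track's first position
    (not cumulative path length), so the oscillatory component averages out
    of the least-squares slope.
    """
    if len(track) < 3:
        raise InsufficientDataError(
            f"track {track.cardioblast_id}: need >= 3 samples for a speed fit"
        )
    t_hr = (track.frames - track.frames[0]) * frame_interval / 3600.0
    d = np.linalg.norm(track.xy - track.xy[0], axis=1)
    slope = np.polyfit(t_hr, d, 1)[0]
    return float(slope)


def estimate_midline(tracks: EmbryoTracks) -> float:
    """Midline x: mean over frames of the midpoint between row mean x positions."""
    left = tracks.by_row("left")
    right = tracks.by_row("right")
    if not left or not right:
        raise ValidationError("midline estimate requires both rows")

    def row_mean_by_frame(row):
        s = pd.concat([pd.Series(t.x, index=t.frames) for t in row])
        return s.groupby(level=0).mean()

    lm = row_mean_by_frame(left)
    rm = row_mean_by_frame(right)
    mid = (lm + rm) / 2.0  # aligned on common frames
    mid = mid.dropna()
    if mid.empty:
        raise ValidationError("rows share no common frames for the midline estimate")
    return float(mid.mean())


def medial_position(track: NucleusTrack, midline_x: float) -> np.ndarray:
    """Signed medial position: increases as the nucleus approaches the midline."""
    sign = -math.copysign(1.0, track.x[0] - midline_x)
    return sign * (track.x - midline_x)


def medial_velocity(
    track: NucleusTrack, midline_x: float, frame_interval: float = 15.0
) -> np.ndarray:
    """Finite-difference medial velocity, μm/min; positive = toward midline.

    Element i is the velocity over the interval frames[i] -> frames[i+1].
    """
    if len(track) < 2:
        raise InsufficientDataError("need >= 2 samples for a velocity")
    m = medial_position(track, midline_x)
    dt_min = np.diff(track.frames) * frame_interval / 60.0
    return np.diff(m) / dt_min


def oscillation_period(
    velocity: np.ndarray,
    frame_interval: float = 15.0,
    max_lag_fraction: float = 0.5,
) -> float:
    """Oscillation period from the first qualifying autocorrelation peak, minutes.

    The velocity series is mean-subtracted and the biased autocorrelation
    estimator (normalisation by the series length) is evaluated up to
    ``max_lag_fraction`` of the series length.  The period is the lag of the
    first local maximum whose value is positive and exceeds the 3/sqrt(n)
    noise band, refined by 3-point parabolic interpolation.  Returns NaN when
    no peak qualifies — a white-noise velocity trace has no period.
    """
    v = np.asarray(velocity, dtype=float)
    if v.ndim != 1 or len(v) < 8:
        raise InsufficientDataError("need >= 8 velocity samples for a period estimate")
    n = len(v)
    v = v - v.mean()
    var = float(np.dot(v, v)) / n
    if var == 0.0:
        return float("nan")
    max_lag = int(max_lag_fraction * n)
    acf = np.array([np.dot(v[: n - lag], v[lag:]) / (n * var) for lag in range(max_lag + 1)])
    threshold = 3.0 / math.sqrt(n)
    dt_min = frame_interval / 60.0
    # first local maximum from lag 2 (skip the zero-lag shoulder)
    for lag in range(2, max_lag):
        if acf[lag] >= acf[lag - 1] and acf[lag] >= acf[lag + 1] and acf[lag] > threshold:
            denom = acf[lag - 1] - 2.0 * acf[lag] + acf[lag + 1]
            delta = 0.0 if denom == 0.0 else 0.5 * (acf[lag - 1] - acf[lag + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            return (lag + delta) * dt_min
    return float("nan")


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; edges use a shrinking window."""
    if window <= 1:
        return x.astype(float)
    half = window // 2
    out = np.empty(len(x))
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def _alternating_extrema(ms: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices and types (+1 max, -1 min) of all turning points of ``ms``.

    The trace endpoints are included, typed opposite to the adjacent
    extremum, so that every run bounds an excursion.  Flat segments inherit
    the preceding slope sign.  Returns empty lists for a constant trace.
    """
    d = np.sign(np.diff(ms))
    for i in range(1, len(d)):
        if d[i] == 0:
            d[i] = d[i - 1]
    nz = d[d != 0]
    if len(nz) == 0:
        return [], []
    if d[0] == 0:
        d[: np.argmax(d != 0)] = nz[0]
    idx = [0]
    typ = [-int(nz[0])]  # rising start => the start point acts as a minimum
    for i in range(1, len(d)):
        if d[i] != d[i - 1]:
            idx.append(i)
            typ.append(int(d[i - 1]))  # was rising: maximum
    idx.append(len(ms) - 1)
    typ.append(int(d[-1]))
    return idx, typ


def step_decomposition(
    track: NucleusTrack, midline_x: float, config: RunConfig | None = None
) -> StepDecomposition:
    """Decompose the medial trajectory into medial and lateral steps.

    Turning points of the smoothed medial position are located, then
    excursions smaller than ``step_prominence`` (measured on the raw
    positions) are pruned smallest-first, merging the adjacent runs — the
    classic turning-point filter.  A medial step is the surviving excursion
    from a local minimum to the next maximum; a lateral step the reverse.
    Amplitudes are read from the raw positions at the turning indices, since
    the moving average attenuates sharp extrema.  For a monotone track the
    whole displacement counts as a single step and the opposite amplitude is
    zero.
    """
    config = config or RunConfig()
    if len(track) < 8:
        raise InsufficientDataError(
            f"track {track.cardioblast_id}: need >= 8 samples for step decomposition"
        )
    m = medial_position(track, midline_x)
    ms = _smooth(m, config.smoothing_window)
    idx, typ = _alternating_extrema(ms)

    # refine turning indices to the raw extremum within the half-window:
    # smoothing flattens sharp vertices, so the smoothed turning point can
    # sit a sample off the true one, badly underestimating the excursion
    half = config.smoothing_window // 2
    if half:
        for j, (i, t) in enumerate(zip(idx, typ)):
            lo = max(0, i - half) if j == 0 or i - half > idx[j - 1] else idx[j - 1] + 1
            hi = min(len(m), i + half + 1)
            if j + 1 < len(idx):
                hi = min(hi, idx[j + 1])
            window = m[lo:hi]
            idx[j] = lo + int(np.argmax(t * window))

    # prune sub-threshold excursions, smallest raw amplitude first
    while len(idx) >= 2:
        amps = np.abs(np.diff(m[idx]))
        j = int(np.argmin(amps))
        if amps[j] >= config.step_prominence:
            break
        del idx[j : j + 2]
        del typ[j : j + 2]

    medial_steps: list[float] = []
    lateral_steps: list[float] = []
    for i0, i1, t1 in zip(idx, idx[1:], typ[1:]):
        amp = m[i1] - m[i0]
        if t1 == 1 and amp > 0:  # rise into a maximum: medial step
            medial_steps.append(amp)
        elif t1 == -1 and amp < 0:  # fall into a minimum: lateral step
            lateral_steps.append(-amp)

    if not medial_steps and not lateral_steps:
        log.warning("track %s: zero detected steps", track.cardioblast_id)
        return StepDecomposition(float("nan"), float("nan"), float("nan"), 0, 0)
    med = float(np.mean(medial_steps)) if medial_steps else 0.0
    lat = float(np.mean(lateral_steps)) if lateral_steps else 0.0
    return StepDecomposition(med, lat, med - lat, len(medial_steps), len(lateral_steps))


def per_cardioblast_metrics(tracks: EmbryoTracks, config: RunConfig | None = None) -> pd.DataFrame:
    """One OscillationMetrics row per analyzable cardioblast."""
    config = config or RunConfig()
    midline = estimate_midline(tracks)
    dt = tracks.meta.frame_interval
    rows = []
    for t in tracks.tracks:
        try:
            speed = migration_speed(t, dt)
            v = medial_velocity(t, midline, dt)
            period = oscillation_period(v, dt, config.max_autocorr_lag_fraction)
            steps = step_decomposition(t, midline, config)
        except InsufficientDataError as exc:
            log.warning("skipping track %s: %s", t.cardioblast_id, exc)
            continue
        rows.append(
            {
                "cardioblast_id": t.cardioblast_id,
                "row": t.row,
                "speed": speed,
                "period": period,
                "medial_amp": steps.medial_amp,
                "lateral_amp": steps.lateral_amp,
                "net_medial_step": steps.net_medial_step,
                "n_medial_steps": steps.n_medial_steps,
                "n_lateral_steps": steps.n_lateral_steps,
            }
        )
    if not rows:
        raise InsufficientDataError(f"{tracks.meta.embryo_id}: no analyzable tracks")
    return pd.DataFrame(rows)


def embryo_oscillation_summary(
    tracks: EmbryoTracks, config: RunConfig | None = None
) -> dict[str, float]:
    """Embryo means of each per-cardioblast metric.

    Cardioblasts with a missing period are excluded from the period mean
    only; all other fields average over every analyzable cardioblast.
    """
    df = per_cardioblast_metrics(tracks, config)
    out = {
        "n_cardioblasts": float(len(df)),
        "speed": float(df["speed"].mean()),
        "period": float(df["period"].mean(skipna=True)),
        "medial_amp": float(df["medial_amp"].mean()),
        "lateral_amp": float(df["lateral_amp"].mean()),
        "net_medial_step": float(df["net_medial_step"].mean()),
        "n_medial_steps": float(df["n_medial_steps"].mean()),
        "n_lateral_steps": float(df["n_lateral_steps"].mean()),
    }
    return out
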