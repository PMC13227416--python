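"""Readers and writers for the package's plain-text formats and TIFF stacks.

Track tables are delimited files with header ``cardioblast_id,row,frame,x,y``
(coordinates in μm).  Lumen annotations use a transparent line-oriented
schema — one record per frame::

    # cardiodyn-lumen v1
    <frame_index> x1 y1 x2 y2 ... xn yn

Both formats round-trip losslessly to 1e-9 μm.  Image stacks are standard
multi-frame grayscale TIFFs read through tifffile.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import EmbryoMeta, EmbryoTracks, LumenSeries, NucleusTrack, RunConfig
from .errors import ConfigError, InputFormatError, ValidationError

log = logging.getLogger("cardiodyn")

TRACK_COLUMNS = ["cardioblast_id", "row", "frame", "x", "y"]


# ---------------------------------------------------------------------------
# track tables


def read_tracks(path: str | Path, meta: EmbryoMeta) -> EmbryoTracks:
    """Read a delimited track table into :class:`EmbryoTracks`.

    Samples are grouped by ``cardioblast_id`` and sorted by frame; frames
    duplicated within a track are rejected.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise InputFormatError(f"{path}: cannot parse track table: {exc}") from exc
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    tracks = []
    for cb_id, grp in df.groupby("cardioblast_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) == 0):
            raise ValidationError(f"{path}: duplicate frame in track {cb_id}")
        rows = grp["row"].unique()
        if len(rows) != 1:
            raise ValidationError(f"{path}: track {cb_id} has inconsistent row labels")
        tracks.append(
            NucleusTrack(
                cardioblast_id=str(cb_id),
                row=str(rows[0]),
                frames=frames,
                xy=grp[["x", "y"]].to_numpy(),
            )
        )
    return EmbryoTracks(meta=meta, tracks=tracks)


def write_tracks(tracks: EmbryoTracks, path: str | Path) -> None:
    rows = []
    for t in tracks.tracks:
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append((t.cardioblast_id, t.row, int(f), x, y))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# lumen annotations

_LUMEN_MAGIC = "# cardiodyn-lumen v1"


def read_lumen_annotations(path: str | Path, meta: EmbryoMeta) -> LumenSeries:
    """Read the line-oriented lumen annotation format into a LumenSeries."""
    frames: list[tuple[int, np.ndarray]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            try:
                idx = int(tokens[0])
                coords = np.array([float(v) for v in tokens[1:]])
            except ValueError as exc:
                raise InputFormatError(f"{path}:{ln}: unparseable record: {exc}") from exc
            if len(coords) % 2 != 0:
                raise InputFormatError(f"{path}:{ln}: odd coordinate count for frame {idx}")
            frames.append((idx, coords.reshape(-1, 2)))
    # LumenSeries validates polygon simplicity / vertex counts per frame
    return LumenSeries(meta=meta, frames=frames)


def write_lumen_annotations(series: LumenSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_LUMEN_MAGIC + "\n")
        for idx, verts in series.frames:
            flat = " ".join(f"{v:.12g}" for v in verts.ravel())
            fh.write(f"{idx} {flat}\n")


# ---------------------------------------------------------------------------
# image stacks


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-frame grayscale TIFF as a (frames, height, width) array."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            photometric = page.photometric
            if photometric not in (
                tifffile.PHOTOMETRIC.MINISBLACK,
                tifffile.PHOTOMETRIC.MINISWHITE,
            ):
                raise InputFormatError(f"{path}: not a grayscale stack ({photometric!r})")
            arr = tif.asarray()
    except InputFormatError:
        raise
    except Exception as exc:  # tifffile raises assorted types on corrupt files
        raise InputFormatError(f"{path}: unreadable TIFF: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InputFormatError(f"{path}: expected 2-D or 3-D grayscale data, got {arr.shape}")
    return arr


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


# ---------------------------------------------------------------------------
# configuration


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; every field optional with defaults."""
    if path is None:
        return RunConfig()
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    section = raw.get("run", raw)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(section) - known - {"cohort"}
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
    kwargs = {k: v for k, v in section.items() if k in known}
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValidationError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
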