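"""File formats and core containers.

Conventions (fixed across the package):

* Images are single-channel, time-ordered stacks ``(frames, height, width)``,
  written as multi-page TIFF with a JSON sidecar carrying the physical
  metadata (``pixel_size_um``, ``frame_interval_s``).
* Pixel coordinates are 0-based and refer to pixel *centers*: the pixel with
  index ``i`` covers the interval ``[i - 0.5, i + 0.5]``.
* Particle-trajectory tables are CSV with columns
  ``track_id, frame, x_px, y_px, intensity_au`` (frame is 1-based;
  ``intensity_au`` is the raw 3x3 window sum for detector output, or the
  background-subtracted window-equivalent signal for simulator fast-path
  output).
* Cell-track tables are CSV with columns ``cell_id, frame, x_um, y_um``;
  the chemoattractant gradient axis is +x.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("nanospt")

DEFAULT_PIXEL_SIZE_UM = 0.1
DEFAULT_FRAME_INTERVAL_S = 0.1

TRACK_COLUMNS = ["track_id", "frame", "x_px", "y_px", "intensity_au"]
CELL_TRACK_COLUMNS = ["cell_id", "frame", "x_um", "y_um"]


@dataclass
class ImageStack:
    """Time-ordered 2-D intensity frames with physical metadata."""

    frames: np.ndarray  # (n_frames, height, width)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("ImageStack.frames must be 3-D (frames, y, x)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    frames = stack.frames
    if frames.dtype != np.uint16:
        frames = np.clip(np.rint(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "n_frames": int(frames.shape[0]),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF stack; metadata from the sidecar or defaults."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = _sidecar_path(path)
    pixel_size, interval = DEFAULT_PIXEL_SIZE_UM, DEFAULT_FRAME_INTERVAL_S
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = float(meta.get("pixel_size_um", pixel_size))
        interval = float(meta.get("frame_interval_s", interval))
    else:
        logger.warning(
            "no metadata sidecar for %s; assuming pixel_size_um=%g, "
            "frame_interval_s=%g",
            path, pixel_size, interval,
        )
    return ImageStack(frames=frames, pixel_size_um=pixel_size, frame_interval_s=interval)


class TrackValidationError(ValueError):
    """Raised for malformed trajectory tables; message lists offending rows."""


def validate_tracks(df: pd.DataFrame, id_col: str = "track_id") -> pd.DataFrame:
    """Check trajectory-table invariants.

    Frames must be strictly increasing within each track in file order and
    no ``(id, frame)`` pair may repeat.  Offending 0-based data-row indices
    are listed in the raised error.
    """
    required = {id_col, "frame"}
    missing = required - set(df.columns)
    if missing:
        raise TrackValidationError(f"missing required columns: {sorted(missing)}")
    bad_rows: list[int] = []
    dup = df.duplicated(subset=[id_col, "frame"], keep="first")
    bad_rows.extend(df.index[dup].tolist())
    # out-of-order frames within a track, judged in file order
    order_ok = df.groupby(id_col, sort=False)["frame"].diff()
    bad_rows.extend(df.index[order_ok.notna() & (order_ok <= 0) & ~dup].tolist())
    if bad_rows:
        raise TrackValidationError(
            f"invalid trajectory rows (duplicate or out-of-order frames) at "
            f"0-based rows: {sorted(set(bad_rows))[:50]}"
        )
    return df


def write_tracks(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_tracks(df)
    df.to_csv(path, index=False)
    return path


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read and validate a particle-trajectory CSV."""
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise TrackValidationError(f"{path}: missing columns {sorted(missing)}")
    if "intensity_au" not in df.columns:
        df["intensity_au"] = np.nan
    validate_tracks(df)
    df["frame"] = df["frame"].astype(int)
    return df


def write_cell_tracks(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_tracks(df, id_col="cell_id")
    df.to_csv(path, index=False)
    return path


def read_cell_tracks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CELL_TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise TrackValidationError(f"{path}: missing columns {sorted(missing)}")
    validate_tracks(df, id_col="cell_id")
    df["frame"] = df["frame"].astype(int)
    return df


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
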