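"""TIFF / CSV / YAML / JSON input-output for the pipeline.

Images travel as plain multi-page TIFF (one page per frame); OME metadata in
input files is accepted and ignored.  Tables are comma-separated UTF-8 CSV
with a header row, '.' decimal, and units encoded in column names (tau_s,
times_s, ...).  Configs are YAML; manifests JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .stack import ImageStack

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_stack(
    path: PathLike,
    frame_interval_s: Optional[float] = None,
    times_s: Optional[Sequence[float]] = None,
    channel_role: str = "scaffold",
    n_z: Optional[int] = None,
) -> ImageStack:
    """Read a multi-page TIFF as an :class:`ImageStack`.

    Intensities are returned as stored (no rescaling).  Acquisition times come
    from ``times_s`` or, failing that, ``frame_interval_s``; multi-frame stacks
    with neither raise an explicit error.  With ``n_z`` set, pages are
    interpreted as ``frames x Z`` and reshaped to ``(T, Z, Y, X)``.
    """
    path = Path(path)
    pixels = np.asarray(tifffile.imread(path))
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3:
        raise ValueError(f"{path}: expected 2-D pages, got array of shape {pixels.shape}")

    if n_z is not None:
        if n_z < 1 or pixels.shape[0] % n_z:
            raise ValueError(
                f"{path}: {pixels.shape[0]} pages do not factor into Z={n_z} planes"
            )
        pixels = pixels.reshape(pixels.shape[0] // n_z, n_z, *pixels.shape[1:])

    n_frames = pixels.shape[0]
    if times_s is not None:
        times = np.asarray(times_s, dtype=np.float64)
    elif frame_interval_s is not None:
        times = np.arange(n_frames) * float(frame_interval_s)
    elif n_frames == 1:
        times = np.zeros(1)
    else:
        raise ValueError(
            f"{path}: {n_frames}-frame stack needs times_s or frame_interval_s "
            "(TIFF tags carry no frame timing)"
        )
    return ImageStack(pixels, times, channel_role)


def write_stack(path: PathLike, stack: ImageStack) -> Path:
    """Write a stack as multi-page float32 TIFF, one page per frame (Z flattened)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pixels = stack.pixels
    if stack.has_z:
        pixels = pixels.reshape(-1, *pixels.shape[-2:])
    tifffile.imwrite(path, pixels.astype(np.float32), photometric="minisblack")
    return path


def write_mask(path: PathLike, mask: np.ndarray) -> Path:
    """Write a binary mask (or per-frame mask stack) as 8-bit TIFF (255 = true)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)),
                     photometric="minisblack")
    return path


def read_mask(path: PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path))) > 0


def write_table(path: PathLike, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def save_config(path: PathLike, config: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path


def load_config(path: PathLike) -> dict:
    with open(Path(path), encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def sha256_file(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(Path(path), "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    """Stable hash of a config mapping (canonical JSON, sorted keys)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path: PathLike, manifest: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
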