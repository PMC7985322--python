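"""In-memory container for fluorescence timelapse stacks.

An :class:`ImageStack` holds per-frame pixel data with acquisition times and a
channel role.  Axis order is ``(frame, Y, X)`` or, before maximal projection,
``(frame, Z, Y, X)``; coordinates are 0-based and row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

CHANNEL_ROLES = ("scaffold", "disruptor", "marker")


@dataclass
class ImageStack:
    """A fluorescence timelapse (optionally multi-Z) single-channel stack.

    Parameters
    ----------
    pixels:
        Array of shape ``(T, Y, X)`` or ``(T, Z, Y, X)`` with nonnegative,
        finite intensities in arbitrary units.
    times_s:
        Acquisition time of each frame, seconds, strictly increasing.
    channel_role:
        Which biological channel this stack carries: the condensate-forming
        ``scaffold`` protein, the recruited ``disruptor`` ligand, or an
        auxiliary ``marker``.
    """

    pixels: np.ndarray
    times_s: np.ndarray
    channel_role: str = "scaffold"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.pixels.ndim not in (3, 4):
            raise ValueError(
                f"pixels must be (T, Y, X) or (T, Z, Y, X), got shape {self.pixels.shape}"
            )
        if self.times_s.ndim != 1 or len(self.times_s) != self.pixels.shape[0]:
            raise ValueError(
                f"times_s length {self.times_s.shape} does not match "
                f"frame count {self.pixels.shape[0]}"
            )
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(
                f"channel_role must be one of {CHANNEL_ROLES}, got {self.channel_role!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def has_z(self) -> bool:
        return self.pixels.ndim == 4

    @property
    def frame_shape(self) -> tuple:
        return self.pixels.shape[-2:]

    @property
    def frame_interval_s(self) -> Optional[float]:
        """Median frame spacing, or None for single-frame stacks."""
        if self.n_frames < 2:
            return None
        return float(np.median(np.diff(self.times_s)))

    def frame(self, index: int) -> np.ndarray:
        return self.pixels[index]

    def with_pixels(self, pixels: np.ndarray) -> "ImageStack":
        return replace(self, pixels=pixels)
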