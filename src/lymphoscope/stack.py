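"""Calibrated dynamic image stacks.

The central in-memory container is :class:`ImageStack`: a 3-D intensity
array ordered (row, col, frame) together with the two calibrations every
downstream quantity needs — the pixel pitch (mm/pixel, square pixels) and
the frame interval (s/frame).  Physical positions are pixel-centre times
pixel pitch with 0-based indices; times are frame index times frame
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A calibrated (row, col, frame) fluorescence image stack.

    Parameters
    ----------
    data:
        Intensity array of shape ``(rows, cols, frames)`` in camera counts
        (or dimensionless units for processed stacks).
    pixel_pitch:
        Physical size of one pixel, mm/pixel.  Must be positive.
    frame_interval:
        Time between consecutive frames, s.  Must be positive.
    band:
        Spectral band label, ``"NIR"`` or ``"SWIR"`` (free-form for
        processed outputs).
    """

    data: np.ndarray
    pixel_pitch: float = 0.1
    frame_interval: float = 0.1
    band: str = "SWIR"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:  # single frame
            self.data = self.data[:, :, None]
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3-D (row, col, frame), got {self.data.ndim}-D")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def frame(self, index: int) -> np.ndarray:
        """Return a single 2-D frame (a view)."""
        return self.data[:, :, index]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame, s."""
        return np.arange(self.n_frames) * self.frame_interval
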