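"""Two-channel 3D image stacks and their TIFF round trip.

A stack holds an *outline* channel (membrane marker or PI stain) and a
*marker* channel (polarity-marker signal) with voxel-size metadata.  On
disk it is a multi-page TIFF with axes (z, channel, y, x).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

CHANNELS = ("outline", "marker")


@dataclass
class ImageStack:
    """Two-channel intensity volume with pixel-size metadata.

    Parameters
    ----------
    outline, marker : ndarray, shape (z, y, x)
        Cell-outline and polarity-marker channels; same shape, non-negative.
    pixel_size : float
        Lateral μm per pixel.
    z_step : float
        Axial μm per slice.
    """

    outline: np.ndarray
    marker: np.ndarray
    pixel_size: float
    z_step: float = 1.0

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=np.float32)
        self.marker = np.asarray(self.marker, dtype=np.float32)
        if self.outline.ndim != 3 or self.outline.shape != self.marker.shape:
            raise ValueError("channels must be 3D (z, y, x) arrays of identical shape")
        if self.outline.shape[0] < 1:
            raise ValueError("stack needs at least one z-slice")
        if (self.outline < 0).any() or (self.marker < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_slices(self) -> int:
        return self.outline.shape[0]

    @property
    def shape_yx(self) -> tuple:
        return self.outline.shape[1:]

    def write(self, path) -> None:
        data = np.stack([self.outline, self.marker], axis=1)  # (z, c, y, x)
        tifffile.imwrite(
            Path(path),
            data.astype(np.float32),
            imagej=True,
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
            metadata={"axes": "ZCYX", "spacing": self.z_step, "unit": "um"},
        )

    @classmethod
    def read(cls, path) -> "ImageStack":
        with tifffile.TiffFile(Path(path)) as tf:
            data = tf.asarray()
            pixel_size = 1.0
            z_step = 1.0
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num:
                    pixel_size = den / num
            meta = tf.imagej_metadata or {}
            z_step = float(meta.get("spacing", 1.0))
        if data.ndim == 3:  # single slice written as (c, y, x)
            data = data[None]
        if data.ndim != 4 or data.shape[1] != 2:
            raise ValueError(f"expected (z, 2, y, x) TIFF, got shape {data.shape}")
        return cls(outline=data[:, 0], marker=data[:, 1], pixel_size=pixel_size, z_step=z_step)
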