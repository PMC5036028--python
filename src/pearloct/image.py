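"""Grayscale B-scan container and file I/O.

A B-scan is a 2-D depth x lateral cross-section: row 0 is the shallowest
depth, rows increase downward into the sample. Pixels are kept as float64
gray levels on the native bit-depth scale (0..255 for 8-bit, 0..65535 for
16-bit) so intermediate stages can carry fractional values without
quantisation; files are read from and written to ordinary TIFF/PNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

#: axial (depth) pixel pitch of the acquisition system, micrometres
DEFAULT_AXIAL_PITCH_UM = 3.48
#: lateral pixel pitch, micrometres
DEFAULT_LATERAL_PITCH_UM = 6.73


@dataclass
class BScanImage:
    """2-D grayscale B-scan with bit depth and pixel-pitch metadata."""

    pixels: np.ndarray
    bit_depth: int = 8
    axial_pitch: float = DEFAULT_AXIAL_PITCH_UM
    lateral_pitch: float = DEFAULT_LATERAL_PITCH_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"B-scan must be 2-D, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > self.max_gray
        ):
            raise ValueError(
                f"pixel values outside [0, {self.max_gray}] for {self.bit_depth}-bit image"
            )

    @property
    def max_gray(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "BScanImage":
        """New image sharing this one's metadata."""
        return replace(self, pixels=pixels)

    def to_uint(self) -> np.ndarray:
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        return np.clip(np.rint(self.pixels), 0, self.max_gray).astype(dtype)


def load_image(path: str | Path) -> BScanImage:
    """Read an 8- or 16-bit grayscale TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # collapse trivial channel axes
        if arr.shape[2] in (3, 4) and np.ptp(arr[..., :3], axis=2).max() == 0:
            arr = arr[..., 0]
        else:
            raise ValueError(f"{path}: expected grayscale, got shape {arr.shape}")
    if arr.dtype == np.uint16:
        depth = 16
    elif arr.dtype == np.uint8 or arr.dtype == bool:
        depth = 8
    else:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    return BScanImage(pixels=arr.astype(np.float64), bit_depth=depth)


def save_image(img: BScanImage, path: str | Path) -> Path:
    """Write as grayscale TIFF or PNG, quantised to the native bit depth."""
    path = Path(path)
    data = img.to_uint()
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        Image.fromarray(data).save(path)
    return path
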