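"""Grayscale image container and file I/O.

Angiograms arrive as 8- or 16-bit grayscale PNG/TIFF. Internally every
image is a float64 array normalized to [0, 1]; the pixel coordinate
convention throughout the package is (x, y) with x = column index,
y = row index, 0-based, integer pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["GrayImage", "load_image", "save_image", "InputError"]


class InputError(ValueError):
    """Unreadable, empty or otherwise invalid input image."""


@dataclass
class GrayImage:
    """2D scalar intensity field with values in [0, 1]."""

    pixels: np.ndarray
    bit_depth: int = 8
    source: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("image must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("image contains non-finite intensities")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def inverted(self) -> "GrayImage":
        """Intensity-flipped copy (bright vessels <-> dark vessels)."""
        return GrayImage(1.0 - self.pixels, bit_depth=self.bit_depth,
                         source=self.source)


def load_image(path: str | Path) -> GrayImage:
    """Read an 8/16-bit grayscale PNG or TIFF, normalized to [0, 1].

    RGB(A) inputs are converted by averaging the color channels.
    """
    try:
        raw = iio.imread(Path(path))
    except Exception as exc:  # pragma: no cover - backend specific
        raise InputError(f"cannot read image {path!r}: {exc}") from exc
    if raw.size == 0:
        raise InputError(f"zero-sized image: {path!r}")
    orig_dtype = raw.dtype
    if raw.ndim == 3:  # luminance average over color channels
        raw = raw[..., :3].astype(np.float64).mean(axis=2)
    if raw.ndim != 2:
        raise InputError(f"unsupported image dimensionality {raw.ndim}")
    if np.issubdtype(orig_dtype, np.integer):
        bit_depth = 16 if orig_dtype.itemsize >= 2 else 8
        scale = float(2 ** bit_depth - 1)
        pixels = raw.astype(np.float64) / scale
    else:  # float TIFF: assume already on a [0, 1]-like scale
        bit_depth = 32
        pixels = raw.astype(np.float64)
        top = pixels.max()
        if top > 1.0:
            pixels = pixels / top
    return GrayImage(pixels, bit_depth=bit_depth, source=str(path))


def save_image(img: GrayImage | np.ndarray, path: str | Path,
               bit_depth: int = 8) -> None:
    """Write an image as 8-bit PNG, 16-bit or 32-bit float TIFF."""
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    path = Path(path)
    if bit_depth == 32:
        iio.imwrite(path, arr.astype(np.float32))
        return
    top = float(2 ** bit_depth - 1)
    quantized = np.clip(np.rint(arr * top), 0, top)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    iio.imwrite(path, quantized.astype(dtype))
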