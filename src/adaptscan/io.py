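"""Image file I/O boundaries.

Internally every image is a float array of normalized intensities in [0, 1]
(quantization is kept out of the processing chain); integer formats appear
only here.  Scans and truth images are written as 16-bit grayscale TIFF,
masks as 8-bit PNG (255 = HIA, 0 = filter region).
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio
import tifffile

from .mask_gen import BinaryMask

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]


def write_image(path, image, bit_depth: int = 16) -> None:
    """Write a normalized image as a 16-bit (or 8-bit) grayscale TIFF.

    Values are clipped to [0, 1] (detector saturation) and scaled to the
    full integer range.
    """
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bit_depth == 16:
        tifffile.imwrite(path, np.round(image * 65535).astype(np.uint16))
    elif bit_depth == 8:
        tifffile.imwrite(path, np.round(image * 255).astype(np.uint8))
    else:
        raise ValueError("bit_depth must be 8 or 16")


def read_image(path) -> np.ndarray:
    """Read a grayscale image file and normalize to [0, 1] floats."""
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:  # collapse trivial channel axes
        raw = raw.mean(axis=-1)
    if raw.dtype == np.uint16:
        return raw.astype(float) / 65535.0
    if raw.dtype == np.uint8:
        return raw.astype(float) / 255.0
    return raw.astype(float)


def write_mask(path, mask) -> None:
    """Write a binary mask as an 8-bit PNG (255 = HIA)."""
    values = np.asarray(getattr(mask, "values", mask), dtype=bool)
    iio.imwrite(path, (values.astype(np.uint8) * 255))


def read_mask(path) -> BinaryMask:
    """Read an 8-bit mask PNG back into a BinaryMask (>= 128 = HIA)."""
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        raw = raw.max(axis=-1)
    return BinaryMask.from_array(raw >= 128)
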