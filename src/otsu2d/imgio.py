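"""Grayscale image and binary mask I/O.

Everything internal is an 8-bit-style integer image: a 2-D ``numpy`` array
of gray levels in ``[0, L-1]`` with ``L = 256``.  Coordinates are 0-based
``(row, column)``; rows run along the direction of illumination change.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

#: Number of gray levels of the internal representation.
LEVELS = 256

# ITU-R BT.601 luminance weights, the standard gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with .5 going up (numpy rounds half to even)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)


def validate_gray(img: np.ndarray, levels: int = LEVELS) -> np.ndarray:
    """Check the gray-image invariants and return the array as int64."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a nonempty 2-D gray image, got shape {arr.shape}")
    arr = arr.astype(np.int64, copy=False)
    if arr.min() < 0 or arr.max() > levels - 1:
        raise ValueError(f"gray levels must lie in [0, {levels - 1}]")
    return arr


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check the binary-mask invariants and return the array as uint8 {0, 1}."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a nonempty 2-D mask, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask values must be exactly 0 or 1")
    return arr.astype(np.uint8, copy=False)


def read_gray(path) -> np.ndarray:
    """Read an image file as an internal gray image.

    RGB(A) input is collapsed to luminance; 16-bit input is rescaled to
    [0, 255]; the result is an int64 array of levels in [0, 255].
    """
    raw = iio.imread(path)
    if raw.size == 0:
        raise ValueError(f"{path}: zero-sized image")
    arr = raw.astype(np.float64)
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[:, :, :3] @ _LUMA
        else:  # single-channel stored with a trailing axis
            arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: unsupported image layout {raw.shape}")
    if raw.dtype == np.uint16 or arr.max() > 255:
        arr = arr * (255.0 / 65535.0)
    img = _round_half_up(arr)
    return validate_gray(np.clip(img, 0, LEVELS - 1))


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit image with foreground 255."""
    arr = validate_mask(mask)
    iio.imwrite(path, (arr * 255).astype(np.uint8))


def mask_from_gray(img: np.ndarray, cutoff: int = 128) -> np.ndarray:
    """Binarise a gray image: pixel >= cutoff becomes foreground (1)."""
    arr = validate_gray(img)
    return (arr >= cutoff).astype(np.uint8)
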