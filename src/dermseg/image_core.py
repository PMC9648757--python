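"""Shared raster types, color-space conversions, and image I/O.

Every pipeline stage works on plain :class:`numpy.ndarray` rasters:

* **RGB image** — ``(H, W, 3)`` ``uint8``, channels in red/green/blue order.
* **Gray image** — ``(H, W)`` ``uint8``.
* **HSV image** — ``(H, W, 3)`` ``float64`` with hue in degrees ``[0, 360)``,
  saturation as a fraction ``[0, 1]`` and value on the integer lattice
  ``[0, 255]`` (kept on the 8-bit scale so intensity transfers are
  lookup-table applications).
* **Binary mask** — ``(H, W)`` ``uint8`` with values in ``{0, 255}``.

The coordinate convention is ``(row, col)``, 0-based, origin at the top-left
corner, everywhere in the package.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image

__all__ = [
    "InvalidInputError",
    "BorderRemovalError",
    "StageError",
    "validate_rgb",
    "validate_gray",
    "validate_mask",
    "rgb_to_gray",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
]

# BT.601 luma weights; the grayscale used for border and hair detection.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class InvalidInputError(ValueError):
    """An input image, mask or configuration violates its contract."""


class BorderRemovalError(RuntimeError):
    """Border detachment failed (degenerate inner rectangle)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check that *img* is a valid ``(H, W, 3)`` uint8 RGB raster."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(f"expected (H, W, 3) RGB image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1 or img.size == 0:
        raise InvalidInputError("empty image")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise InvalidInputError(f"RGB intensities must be integers in [0, 255], got dtype {img.dtype}")
    return img


def validate_gray(img: np.ndarray) -> np.ndarray:
    """Check that *img* is a valid ``(H, W)`` uint8 grayscale raster."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise InvalidInputError(f"expected (H, W) gray image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise InvalidInputError("empty image")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise InvalidInputError(f"gray intensities must be integers in [0, 255], got dtype {img.dtype}")
    return img


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check that *mask* is binary with labels in ``{0, 255}``."""
    mask = validate_gray(mask)
    bad = ~np.isin(mask, (0, 255))
    if bad.any():
        raise InvalidInputError("binary mask may only contain the values 0 and 255")
    return mask


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """BT.601 luma of an RGB image, rounded to the nearest integer.

    ``Y = 0.299 R + 0.587 G + 0.114 B`` per pixel; pure white maps to 255,
    pure black to 0, pure red to round(76.245) = 76.
    """
    img = validate_rgb(img)
    luma = img.astype(np.float64) @ LUMA_WEIGHTS
    return np.rint(luma).clip(0, 255).astype(np.uint8)


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Standard hexcone RGB→HSV conversion.

    Returns a float array with H in degrees [0, 360), S in [0, 1] and V on
    [0, 255].
    """
    from skimage.color import rgb2hsv

    img = validate_rgb(img)
    hsv = rgb2hsv(img)  # all channels on [0, 1]
    out = np.empty_like(hsv)
    out[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    out[..., 1] = hsv[..., 1]
    out[..., 2] = hsv[..., 2] * 255.0
    return out


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse hexcone conversion back to uint8 RGB.

    Round-trips with :func:`rgb_to_hsv` within ±1 per channel.
    """
    from skimage.color import hsv2rgb

    hsv = np.asarray(hsv, dtype=np.float64)
    if hsv.ndim != 3 or hsv.shape[2] != 3:
        raise InvalidInputError(f"expected (H, W, 3) HSV image, got shape {hsv.shape}")
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    if (h < 0).any() or (h >= 360).any():
        raise InvalidInputError("hue must lie in [0, 360)")
    if (s < 0).any() or (s > 1).any():
        raise InvalidInputError("saturation must lie in [0, 1]")
    if (v < 0).any() or (v > 255).any():
        raise InvalidInputError("value must lie in [0, 255]")
    unit = np.stack([h / 360.0, s, v / 255.0], axis=-1)
    rgb = hsv2rgb(unit) * 255.0
    return np.rint(rgb).clip(0, 255).astype(np.uint8)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit image file (BMP/PNG/JPG) as an RGB raster."""
    with Image.open(path) as im:
        return validate_rgb(np.asarray(im.convert("RGB")))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a ground-truth mask; any gray value > 127 counts as lesion."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return np.where(arr > 127, 255, 0).astype(np.uint8)


def write_image(path: str | os.PathLike, img: np.ndarray) -> None:
    Image.fromarray(validate_rgb(img), mode="RGB").save(path)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a binary mask as a single-channel image with values {0, 255}."""
    Image.fromarray(validate_mask(mask), mode="L").save(path)
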