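"""8-bit HSV conversion on the half-degree hue wheel.

All hue values in this package live on a [0, 180) wheel stored in a uint8
channel (one unit = two degrees), with saturation and value scaled to
[0, 255].  This is the common 8-bit machine-vision convention and the one
under which the stem hue band 23-35 denotes yellow-green.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

from ._counters import counters

HUE_LEVELS = 180  # hue wheel size in half-degrees


def _check_rgb8(image: np.ndarray) -> None:
    if not (isinstance(image, np.ndarray) and image.ndim == 3 and image.shape[2] == 3):
        raise ValueError("expected an (H, W, 3) RGB array")
    if image.dtype != np.uint8:
        raise ValueError("expected an 8-bit (uint8) RGB image")


def rgb_to_hsv8(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit HSV (H in [0,180), S/V in [0,255]).

    Increments the ``hsv_conversions`` counter: the pipeline contract is one
    conversion per image.
    """
    _check_rgb8(image)
    counters["hsv_conversions"] += 1
    hsv = _skcolor.rgb2hsv(image)  # floats in [0, 1]
    out = np.empty(image.shape, dtype=np.uint8)
    out[..., 0] = np.round(hsv[..., 0] * HUE_LEVELS).astype(np.int32) % HUE_LEVELS
    out[..., 1] = np.round(hsv[..., 1] * 255.0).astype(np.uint8)
    out[..., 2] = np.round(hsv[..., 2] * 255.0).astype(np.uint8)
    return out


def hsv8_to_rgb(hsv8: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv8` (up to uint8 quantization)."""
    if not (isinstance(hsv8, np.ndarray) and hsv8.ndim == 3 and hsv8.shape[2] == 3):
        raise ValueError("expected an (H, W, 3) HSV array")
    hsv = np.empty(hsv8.shape, dtype=np.float64)
    hsv[..., 0] = hsv8[..., 0] / HUE_LEVELS
    hsv[..., 1] = hsv8[..., 1] / 255.0
    hsv[..., 2] = hsv8[..., 2] / 255.0
    rgb = _skcolor.hsv2rgb(hsv)
    return np.round(rgb * 255.0).astype(np.uint8)
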