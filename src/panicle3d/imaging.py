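"""HSV background masking for raw multi-view images.

Before reconstruction, images of the panicle against the black imaging
chamber are cleaned by thresholding in HSV space: a pixel is kept only if
hue, saturation, and value all fall inside configured ranges.  The default
ranges (H 0-1, S 0-1, V 0.15-1) remove near-black background while keeping
every hue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import rgb2hsv

__all__ = ["RGBImage", "HSVThresholds", "mask_background", "read_image", "write_image"]


@dataclass
class HSVThresholds:
    """Inclusive [low, high] bounds per HSV channel, each channel on [0, 1]."""

    h_range: tuple[float, float] = (0.0, 1.0)
    s_range: tuple[float, float] = (0.0, 1.0)
    v_range: tuple[float, float] = (0.15, 1.0)

    def __post_init__(self) -> None:
        for name in ("h_range", "s_range", "v_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= low <= high <= 1, got ({lo}, {hi})")


@dataclass
class RGBImage:
    """H×W×3 intensity grid in [0, 255] with a boolean retention mask."""

    pixels: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H×W×3, got {self.pixels.shape}")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape[:2]:
                raise ValueError("mask shape must match the pixel grid")


def mask_background(image: RGBImage, thresholds: HSVThresholds | None = None) -> RGBImage:
    """Mask out pixels whose HSV coordinates fall outside the threshold ranges.

    The mask is true exactly where H, S, and V all lie inside their inclusive
    ranges; removed pixels are set to black, retained pixels are unchanged.
    V follows the common "value" definition max(R, G, B)/255, so a pure-black
    pixel has V = 0 and is removed under the default 0.15 value floor.
    """
    if thresholds is None:
        thresholds = HSVThresholds()
    hsv = rgb2hsv(np.asarray(image.pixels, dtype=np.float64) / 255.0)
    keep = np.ones(hsv.shape[:2], dtype=bool)
    for ch, (lo, hi) in enumerate(
        (thresholds.h_range, thresholds.s_range, thresholds.v_range)
    ):
        keep &= (hsv[:, :, ch] >= lo) & (hsv[:, :, ch] <= hi)
    out = np.where(keep[:, :, None], image.pixels, 0)
    return RGBImage(out, keep)


def read_image(path: str | Path) -> RGBImage:
    """Read a PNG/JPEG image as an RGBImage (alpha channel dropped)."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return RGBImage(arr[:, :, :3])


def write_image(image: RGBImage, path: str | Path) -> Path:
    """Write an RGBImage as PNG (masked-out pixels already black)."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, np.asarray(image.pixels, dtype=np.uint8))
    return path
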