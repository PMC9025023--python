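"""Reading and writing of images, masks and label maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = ["GrayImage", "load_gray", "save_mask", "save_labels", "load_labels"]


@dataclass
class GrayImage:
    """8-bit intensity raster with an optional physical scale."""

    pixels: np.ndarray
    mm_per_px: float = 1.0 / 20.0

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def load(cls, path, mm_per_px: float = 1.0 / 20.0) -> "GrayImage":
        return cls(pixels=load_gray(path), mm_per_px=mm_per_px)


def load_gray(path) -> np.ndarray:
    """Load a PNG/TIFF image as 8-bit grayscale (color converted by luminance)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values 0/255."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def save_labels(path, labels: np.ndarray) -> None:
    """Write an instance label map as a 16-bit grayscale PNG."""
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError("labels out of 16-bit range")
    Image.fromarray(arr.astype(np.uint16)).save(path)


def load_labels(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im).astype(np.int32)
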