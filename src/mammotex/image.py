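"""Core image containers: masked 8-bit grayscale mammograms.

All texture analysis in this package operates on a :class:`MammogramImage`,
an 8-bit grayscale pixel matrix paired with a boolean breast-region mask.
Every feature is computed from pixels inside the mask only; the background
(pectoral shadow, labels, air) is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio

__all__ = [
    "MammogramImage",
    "QuantizedImage",
    "quantize_gray_levels",
    "threshold_pmd",
    "read_image",
    "write_image",
]


@dataclass(frozen=True)
class MammogramImage:
    """An 8-bit grayscale image with a binary breast-region mask.

    Parameters
    ----------
    pixels
        Integer matrix with gray values in [0, 255].
    mask
        Boolean matrix of the same shape; True marks the breast region.
    """

    pixels: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        mask = np.asarray(self.mask, dtype=bool)
        if pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D matrix")
        if pixels.shape != mask.shape:
            raise ValueError(
                f"pixel/mask shape mismatch: {pixels.shape} vs {mask.shape}"
            )
        if pixels.min() < 0 or pixels.max() > 255:
            raise ValueError("gray values must lie in [0, 255]")
        if not mask.any():
            raise ValueError("mask must contain at least one breast pixel")
        object.__setattr__(self, "pixels", pixels.astype(np.uint8))
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def masked_values(self) -> np.ndarray:
        """Gray values of the pixels inside the breast mask, flattened."""
        return self.pixels[self.mask]


@dataclass(frozen=True)
class QuantizedImage:
    """Gray levels re-binned to G discrete levels, mask carried through."""

    levels: np.ndarray
    G: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels)
        if levels.max(initial=0) >= self.G:
            raise ValueError("quantized levels must be < G")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


def quantize_gray_levels(image: MammogramImage, G: int) -> QuantizedImage:
    """Quantize 8-bit gray values to ``G`` equal-width levels.

    ``level = floor(gray / (256 / G))``; ``G`` must divide 256 so bins are
    exact. Used before co-occurrence (G=64) and run-length (G=16) analysis.
    """
    if G <= 0 or 256 % G != 0:
        raise ValueError(f"G must be a positive divisor of 256, got {G}")
    width = 256 // G
    levels = (image.pixels.astype(np.int64) // width).astype(np.int64)
    return QuantizedImage(levels=levels, G=G, mask=image.mask)


def threshold_pmd(image: MammogramImage, threshold: int = 128) -> float:
    """Percentage mammographic density by gray-level thresholding.

    Returns ``100 * #(masked pixels with gray >= threshold) / #(masked
    pixels)`` — the automated counterpart of interactive threshold density
    reading, with a fixed cut instead of a per-image reader choice.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    values = image.masked_values()
    if values.size == 0:
        raise ValueError("empty mask: PMD undefined")
    return 100.0 * float(np.count_nonzero(values >= threshold)) / values.size


def read_image(pixel_path: str | Path, mask_path: str | Path) -> MammogramImage:
    """Load an 8-bit grayscale PNG/TIFF and its 0/255 mask PNG."""
    pixels = np.asarray(iio.imread(pixel_path))
    mask = np.asarray(iio.imread(mask_path)) > 0
    return MammogramImage(pixels=pixels, mask=mask)


def write_image(image: MammogramImage, pixel_path: str | Path,
                mask_path: str | Path) -> None:
    """Write pixels as 8-bit grayscale PNG and mask as 0/255 PNG."""
    iio.imwrite(pixel_path, image.pixels.astype(np.uint8))
    iio.imwrite(mask_path, (image.mask.astype(np.uint8) * 255))
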