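"""Regional texture features.

At each of eight gray thresholds the masked image is binarized (gray >=
threshold, inside the mask only) and decomposed into 4-connected regions.
Six statistics summarise the resulting region set: log(1 + number of
regions), mean and SD of region area, mean compactness 4*pi*A/P^2, the
largest region's share of the breast area, and the mean of the regions'
mean gray values. The top threshold 256 is unreachable for 8-bit data, so
its region set is empty and all six statistics default to 0 — it anchors
the feature scale at the "no dense tissue at all" end.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from ..image import MammogramImage

__all__ = ["regional_features", "regional_feature_names", "THRESHOLDS"]

THRESHOLDS = (32, 64, 96, 128, 160, 192, 224, 256)
_STATS = ("log_count", "mean_area", "sd_area", "mean_compactness",
          "largest_fraction", "mean_gray")


def regional_feature_names() -> list[str]:
    return [f"regional.{s}.t{t:03d}" for t in THRESHOLDS for s in _STATS]


def regional_features(image: MammogramImage) -> dict[str, float]:
    """48 region statistics (6 per binarization threshold)."""
    mask_size = int(np.count_nonzero(image.mask))
    if mask_size == 0:
        raise ValueError("empty mask")
    pixels = image.pixels.astype(float)
    out: dict[str, float] = {}
    for t in THRESHOLDS:
        binary = image.mask & (image.pixels.astype(int) >= t)
        vals = dict.fromkeys(_STATS, 0.0)
        if binary.any():
            labels = measure.label(binary, connectivity=1)
            props = measure.regionprops(labels, intensity_image=pixels)
            areas = np.array([p.area for p in props], dtype=float)
            compact = []
            for p in props:
                perim = p.perimeter
                # A single pixel has zero crofton perimeter; treat it as
                # maximally compact.
                compact.append(4 * np.pi * p.area / perim ** 2
                               if perim > 0 else 1.0)
            vals["log_count"] = float(np.log1p(len(props)))
            vals["mean_area"] = float(areas.mean())
            vals["sd_area"] = float(areas.std())
            vals["mean_compactness"] = float(np.mean(compact))
            vals["largest_fraction"] = float(areas.max() / mask_size)
            vals["mean_gray"] = float(
                np.mean([p.intensity_mean for p in props]))
        for s in _STATS:
            out[f"regional.{s}.t{t:03d}"] = vals[s]
    return out
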