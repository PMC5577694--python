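"""Run-length texture features.

A gray-level run is a maximal string of collinear pixels sharing the same
quantized gray level; runs stop at the mask boundary. The run-length matrix
p(g, l) counts runs of level g and length l along one direction. From it the
family computes the 15 standard statistics — short/long-run emphasis, gray
level and run-length non-uniformity (raw and normalized), run percentage,
gray-level and run-length variance, and the low/high-gray-level emphasis
variants — for each of the four directions (0/45/90/135 degrees), 60
features in all.

Gray-level weights use 1-based levels (g + 1) so the low-gray-level
emphases are defined at level 0.
"""

from __future__ import annotations

import numpy as np

from ..image import QuantizedImage
from .glcm import ORIENTATIONS

__all__ = ["run_length_matrix", "run_length_features",
           "run_length_feature_names"]

_STATS = ("sre", "lre", "gln", "glnn", "rln", "rlnn", "rp", "glv", "rlv",
          "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge")


def run_length_feature_names() -> list[str]:
    return [f"runlength.{s}.a{o:03d}" for o in ORIENTATIONS for s in _STATS]


def _lines(levels: np.ndarray, mask: np.ndarray, orientation: int):
    """Yield (level, mask) 1-D lines along one scan direction."""
    h, w = levels.shape
    if orientation == 0:
        for r in range(h):
            yield levels[r], mask[r]
    elif orientation == 90:
        for c in range(w):
            yield levels[:, c], mask[:, c]
    elif orientation == 45:
        flipped_l, flipped_m = levels[::-1], mask[::-1]
        for d in range(-h + 1, w):
            yield flipped_l.diagonal(d), flipped_m.diagonal(d)
    elif orientation == 135:
        for d in range(-h + 1, w):
            yield levels.diagonal(d), mask.diagonal(d)
    else:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")


def run_length_matrix(q: QuantizedImage, orientation: int) -> np.ndarray:
    """G x L_max run counts along one direction, runs broken by the mask."""
    max_len = max(q.levels.shape)
    counts = np.zeros((q.G, max_len), dtype=np.int64)
    for line, m in _lines(q.levels, q.mask, orientation):
        if not m.any():
            continue
        # Break lines at mask gaps and at level changes simultaneously:
        # a new run starts where the mask turns on or the level changes.
        line = np.asarray(line)
        m = np.asarray(m, dtype=bool)
        idx = np.flatnonzero(m)
        if idx.size == 0:
            continue
        starts = [0]
        for k in range(1, idx.size):
            if idx[k] != idx[k - 1] + 1 or line[idx[k]] != line[idx[k - 1]]:
                starts.append(k)
        starts.append(idx.size)
        for a, b in zip(starts[:-1], starts[1:]):
            counts[line[idx[a]], b - a - 1] += 1
    return counts


def _stats_from_matrix(counts: np.ndarray, n_pixels: int) -> dict[str, float]:
    n_runs = counts.sum()
    if n_runs == 0:
        raise ValueError("no runs: empty mask")
    g = np.arange(1, counts.shape[0] + 1, dtype=float)  # 1-based gray level
    l = np.arange(1, counts.shape[1] + 1, dtype=float)
    r_l = counts.sum(axis=0).astype(float)   # runs per length
    r_g = counts.sum(axis=1).astype(float)   # runs per gray level
    p = counts / n_runs
    mu_g = float((g * r_g).sum() / n_runs)
    mu_l = float((l * r_l).sum() / n_runs)
    gl = np.outer(g, np.ones_like(l))
    ll = np.outer(np.ones_like(g), l)
    return {
        "sre": float((r_l / l ** 2).sum() / n_runs),
        "lre": float((r_l * l ** 2).sum() / n_runs),
        "gln": float((r_g ** 2).sum() / n_runs),
        "glnn": float((r_g ** 2).sum() / n_runs ** 2),
        "rln": float((r_l ** 2).sum() / n_runs),
        "rlnn": float((r_l ** 2).sum() / n_runs ** 2),
        "rp": float(n_runs / n_pixels),
        "glv": float((p * (gl - mu_g) ** 2).sum()),
        "rlv": float((p * (ll - mu_l) ** 2).sum()),
        "lgre": float((r_g / g ** 2).sum() / n_runs),
        "hgre": float((r_g * g ** 2).sum() / n_runs),
        "srlge": float((counts / (gl ** 2 * ll ** 2)).sum() / n_runs),
        "srhge": float((counts * gl ** 2 / ll ** 2).sum() / n_runs),
        "lrlge": float((counts * ll ** 2 / gl ** 2).sum() / n_runs),
        "lrhge": float((counts * gl ** 2 * ll ** 2).sum() / n_runs),
    }


def run_length_features(q: QuantizedImage) -> dict[str, float]:
    """60 run-length features (15 statistics x 4 directions)."""
    n_pixels = int(np.count_nonzero(q.mask))
    if n_pixels == 0:
        raise ValueError("empty mask")
    out: dict[str, float] = {}
    for o in ORIENTATIONS:
        counts = run_length_matrix(q, o)
        for s, val in _stats_from_matrix(counts, n_pixels).items():
            out[f"runlength.{s}.a{o:03d}"] = val
    return out
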