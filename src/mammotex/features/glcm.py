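"""Markovian (co-occurrence) texture features.

A gray-level co-occurrence matrix (GLCM) estimates the joint probability
that two masked pixels at a fixed displacement carry gray levels (i, j).
Both pixels of a pair must lie inside the breast mask; pairs are counted in
both directions, so the matrix is symmetric. From the GLCM at distance 1
and orientations 0/45/90/135 degrees the family computes, per orientation,
the 13 classic Haralick statistics, plus summary statistics of the sum
histogram p_{x+y} and the difference histogram p_{|x-y|}, plus five
orientation-averaged statistics — 93 features in all.

Coordinates are row-major; orientation 0 degrees points east (+x) and 90
degrees north (-row). Logarithms are natural, with 0 * log 0 = 0.
"""

from __future__ import annotations

import numpy as np

from ..image import QuantizedImage

__all__ = ["cooccurrence_matrix", "markovian_features",
           "markovian_feature_names", "ORIENTATIONS"]

ORIENTATIONS = (0, 45, 90, 135)

# (row, col) steps for each orientation, 0 deg = east, 90 deg = north.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_HARALICK = ("asm", "contrast", "correlation", "variance", "idm",
             "sum_average", "sum_variance", "sum_entropy", "entropy",
             "difference_variance", "difference_entropy", "imc1", "imc2")
_SUMHIST = ("mean", "variance", "energy", "entropy")
_DIFFHIST = ("mean", "variance", "energy", "entropy", "inverse_difference")
_AVERAGED = ("contrast", "correlation", "energy", "entropy", "idm")


def markovian_feature_names() -> list[str]:
    names = []
    for o in ORIENTATIONS:
        names += [f"markovian.{s}.a{o:03d}" for s in _HARALICK]
    for o in ORIENTATIONS:
        names += [f"markovian.sumhist.{s}.a{o:03d}" for s in _SUMHIST]
    for o in ORIENTATIONS:
        names += [f"markovian.diffhist.{s}.a{o:03d}" for s in _DIFFHIST]
    names += [f"markovian.avg.{s}" for s in _AVERAGED]
    return names


def cooccurrence_matrix(q: QuantizedImage, distance: int = 1,
                        orientation: int = 0) -> np.ndarray:
    """Symmetric, normalized GxG co-occurrence matrix at one displacement.

    Only pairs with both pixels inside the mask are counted. Raises if the
    mask admits no valid pair at this displacement.
    """
    if orientation not in _OFFSETS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    dr, dc = _OFFSETS[orientation]
    dr, dc = dr * distance, dc * distance
    levels, mask = q.levels, q.mask
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("displacement larger than image: no pixel pairs")
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    if not valid.any():
        raise ValueError("mask admits no co-occurring pixel pair")
    counts = np.zeros((q.G, q.G), dtype=np.int64)
    np.add.at(counts, (a[valid], b[valid]), 1)
    counts = counts + counts.T
    return counts / counts.sum()


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _haralick(P: np.ndarray) -> dict[str, float]:
    G = P.shape[0]
    i = np.arange(G, dtype=float)
    px = P.sum(axis=1)  # = py by symmetry
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    p_sum = np.zeros(2 * G - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), P.ravel())
    p_diff = np.zeros(G)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), P.ravel())
    k_sum = np.arange(2 * G - 1, dtype=float)
    k_diff = np.arange(G, dtype=float)

    out: dict[str, float] = {}
    out["asm"] = float((P ** 2).sum())
    out["contrast"] = float((P * (ii - jj) ** 2).sum())
    if sigma > 0:
        out["correlation"] = float(
            ((ii - mu) * (jj - mu) * P).sum() / sigma2)
    else:
        out["correlation"] = 0.0
    out["variance"] = sigma2
    out["idm"] = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((k_sum * p_sum).sum())
    out["sum_average"] = sum_avg
    out["sum_variance"] = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    out["sum_entropy"] = _entropy(p_sum)
    hxy = _entropy(P.ravel())
    out["entropy"] = hxy
    diff_mean = float((k_diff * p_diff).sum())
    out["difference_variance"] = float(
        ((k_diff - diff_mean) ** 2 * p_diff).sum())
    out["difference_entropy"] = _entropy(p_diff)
    # Information measures of correlation from the marginal entropies.
    hx = _entropy(px)
    outer = np.outer(px, px)
    pos = (P > 0) & (outer > 0)
    hxy1 = float(-(P[pos] * np.log(outer[pos])).sum())
    nzo = outer[outer > 0]
    hxy2 = float(-(nzo * np.log(nzo)).sum())
    out["imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return out


def _hist_stats(p: np.ndarray, with_inverse: bool) -> dict[str, float]:
    k = np.arange(p.size, dtype=float)
    mean = float((k * p).sum())
    out = {
        "mean": mean,
        "variance": float(((k - mean) ** 2 * p).sum()),
        "energy": float((p ** 2).sum()),
        "entropy": _entropy(p),
    }
    if with_inverse:
        out["inverse_difference"] = float((p / (1.0 + k ** 2)).sum())
    return out


def markovian_features(q: QuantizedImage) -> dict[str, float]:
    """93 co-occurrence features at distance 1 over four orientations."""
    G = q.G
    i = np.arange(G, dtype=float)
    out: dict[str, float] = {}
    per_orientation: dict[int, dict[str, float]] = {}
    matrices: dict[int, np.ndarray] = {}
    for o in ORIENTATIONS:
        P = cooccurrence_matrix(q, 1, o)
        matrices[o] = P
        stats = _haralick(P)
        per_orientation[o] = stats
        for s in _HARALICK:
            out[f"markovian.{s}.a{o:03d}"] = stats[s]
    for o in ORIENTATIONS:
        P = matrices[o]
        ii, jj = np.meshgrid(i, i, indexing="ij")
        p_sum = np.zeros(2 * G - 1)
        np.add.at(p_sum, (ii + jj).astype(int).ravel(), P.ravel())
        for s, val in _hist_stats(p_sum, with_inverse=False).items():
            out[f"markovian.sumhist.{s}.a{o:03d}"] = val
    for o in ORIENTATIONS:
        P = matrices[o]
        ii, jj = np.meshgrid(i, i, indexing="ij")
        p_diff = np.zeros(G)
        np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), P.ravel())
        for s, val in _hist_stats(p_diff, with_inverse=True).items():
            out[f"markovian.diffhist.{s}.a{o:03d}"] = val
    for s in _AVERAGED:
        key = "asm" if s == "energy" else s
        out[f"markovian.avg.{s}"] = float(
            np.mean([per_orientation[o][key] for o in ORIENTATIONS]))
    return out
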