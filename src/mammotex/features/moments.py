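"""Moment-based and histogram features of the masked gray-level distribution.

The moment family (76 features) summarises the gray-level distribution
without spatial information: the four central moments (mean, variance,
skewness, kurtosis), the normalized central moments m_k = mu_k / sigma^k for
k = 2..19, and three bounded monotone transformations of each NCM that tame
the explosive growth of high-order moments:

    T1(m) = sign(m) * log(1 + |m|)
    T2(m) = sign(m) * |m|^(1/k)
    T3(m) = m / (1 + |m|)

The histogram family (16 features) is the relative frequency of masked
pixels in 16 equal-width gray bins over [0, 256). When sigma = 0 (constant
region) all standardized moments are defined as 0 so vectors stay finite.
"""

from __future__ import annotations

import numpy as np

from ..image import MammogramImage

__all__ = ["intensity_features", "moment_feature_names",
           "histogram_feature_names"]

_NCM_ORDERS = tuple(range(2, 20))


def moment_feature_names() -> list[str]:
    names = ["moment.mean", "moment.variance", "moment.skewness",
             "moment.kurtosis"]
    names += [f"moment.ncm.k{k:02d}" for k in _NCM_ORDERS]
    for tag in ("slog", "root", "ratio"):
        names += [f"moment.ncm_{tag}.k{k:02d}" for k in _NCM_ORDERS]
    return names


def histogram_feature_names() -> list[str]:
    return [f"histogram.bin{i:02d}" for i in range(16)]


def intensity_features(image: MammogramImage) -> dict[str, float]:
    """76 moment features and 16 histogram features of the masked pixels."""
    v = image.masked_values().astype(float)
    if v.size == 0:
        raise ValueError("empty mask")
    mean = float(v.mean())
    centered = v - mean
    var = float(np.mean(centered ** 2))
    sigma = np.sqrt(var)
    out: dict[str, float] = {"moment.mean": mean, "moment.variance": var}
    if sigma > 0:
        z = centered / sigma
        out["moment.skewness"] = float(np.mean(z ** 3))
        out["moment.kurtosis"] = float(np.mean(z ** 4))
        ncm = {k: float(np.mean(z ** k)) for k in _NCM_ORDERS}
    else:
        out["moment.skewness"] = 0.0
        out["moment.kurtosis"] = 0.0
        ncm = {k: 0.0 for k in _NCM_ORDERS}
    for k, m in ncm.items():
        out[f"moment.ncm.k{k:02d}"] = m
    for k, m in ncm.items():
        out[f"moment.ncm_slog.k{k:02d}"] = float(np.sign(m) * np.log1p(abs(m)))
    for k, m in ncm.items():
        out[f"moment.ncm_root.k{k:02d}"] = float(
            np.sign(m) * abs(m) ** (1.0 / k))
    for k, m in ncm.items():
        out[f"moment.ncm_ratio.k{k:02d}"] = float(m / (1.0 + abs(m)))
    hist, _ = np.histogram(v, bins=16, range=(0, 256))
    freq = hist / v.size
    for i in range(16):
        out[f"histogram.bin{i:02d}"] = float(freq[i])
    return out
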