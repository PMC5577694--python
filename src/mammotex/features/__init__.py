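"""Texture feature extraction: 363 named features in seven families.

The inventory per family is fixed by contract:

================  =====
moment               76
histogram            16
markovian            93
regional             48
runlength            60
fourier              33
wavelet              37
================  =====

``extract_features`` concatenates the families in the order above and
always returns the same 363 names in the same order; the registry
(`feature_names`, `FAMILY_COUNTS`, `family_of`) is data-driven so the
inventory can be revised without touching extractor logic.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd

from ..image import MammogramImage, quantize_gray_levels
from .moments import (intensity_features, moment_feature_names,
                      histogram_feature_names)
from .glcm import (cooccurrence_matrix, markovian_features,
                   markovian_feature_names, ORIENTATIONS)
from .runlength import (run_length_features, run_length_feature_names,
                        run_length_matrix)
from .regional import regional_features, regional_feature_names
from .spectral import (spectral_features, fourier_feature_names,
                       wavelet_feature_names, fourier_features,
                       wavelet_features)

__all__ = [
    "extract_features", "extract_feature_table", "feature_names",
    "family_of", "FAMILY_COUNTS", "intensity_features",
    "cooccurrence_matrix", "markovian_features", "run_length_features",
    "run_length_matrix", "regional_features", "spectral_features",
    "fourier_features", "wavelet_features", "ORIENTATIONS",
    "BASIC_FEATURES",
]

FAMILY_COUNTS = {
    "moment": 76, "histogram": 16, "markovian": 93, "regional": 48,
    "runlength": 60, "fourier": 33, "wavelet": 37,
}

_FAMILY_NAMES = {
    "moment": moment_feature_names(),
    "histogram": histogram_feature_names(),
    "markovian": markovian_feature_names(),
    "regional": regional_feature_names(),
    "runlength": run_length_feature_names(),
    "fourier": fourier_feature_names(),
    "wavelet": wavelet_feature_names(),
}

_ORDER = ("moment", "histogram", "markovian", "regional", "runlength",
          "fourier", "wavelet")

#: Basic intensity features accepted into any analysis without preselection:
#: the four central moments and the 16 histogram bins.
BASIC_FEATURES = tuple(
    ["moment.mean", "moment.variance", "moment.skewness", "moment.kurtosis"]
    + histogram_feature_names()
)


def feature_names(family: str | None = None) -> list[str]:
    """The fixed, ordered feature-name registry (all 363, or one family)."""
    if family is not None:
        return list(_FAMILY_NAMES[family])
    return [n for fam in _ORDER for n in _FAMILY_NAMES[fam]]


def family_of(name: str) -> str:
    """Family tag of a feature name (its prefix up to the first dot)."""
    fam = name.split(".", 1)[0]
    if fam not in FAMILY_COUNTS:
        raise KeyError(f"unknown feature {name!r}")
    return fam


def extract_features(image: MammogramImage) -> pd.Series:
    """All 363 texture features of one masked image, in registry order."""
    values: dict[str, float] = {}
    values.update(intensity_features(image))
    values.update(markovian_features(quantize_gray_levels(image, 64)))
    values.update(regional_features(image))
    values.update(run_length_features(quantize_gray_levels(image, 16)))
    values.update(spectral_features(image))
    ordered = feature_names()
    return pd.Series([values[n] for n in ordered], index=ordered,
                     dtype=float)


def extract_feature_table(images: Iterable[tuple[object, MammogramImage]]
                          ) -> pd.DataFrame:
    """Feature table for a batch of ``(patient_id, image)`` pairs."""
    rows, ids = [], []
    for patient_id, image in images:
        ids.append(patient_id)
        rows.append(extract_features(image))
    table = pd.DataFrame(rows)
    table.insert(0, "patient_id", ids)
    return table.reset_index(drop=True)
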