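"""Fourier and wavelet (spectral) texture features.

Both families work on the image cropped to the mask bounding box, with
pixels outside the mask replaced by the masked mean so the breast outline
does not dominate the spectrum.

Fourier (33): the power spectrum of the mean-subtracted crop is partitioned
into 16 radial annuli of equal width up to the Nyquist frequency (0.5
cycles/pixel) and 16 angular sectors of 11.25 degrees over [0, 180); each
feature is the fraction of total AC power in one bin, plus the
power-weighted mean spectral radius (centroid). Corner frequencies beyond
Nyquist belong to no annulus, so annulus fractions sum to <= 1.

Wavelet (37): a 4-level separable Daubechies-4 decomposition; per level the
energies of the LH/HL/HH detail sub-bands, their fractions of the total
energy, and the Shannon entropies of the normalized squared detail
coefficients, plus the energy of the final approximation. Level 1 is the
finest scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt

from ..image import MammogramImage

__all__ = ["spectral_features", "fourier_feature_names",
           "wavelet_feature_names", "fourier_features", "wavelet_features"]

_N_ANNULI = 16
_N_SECTORS = 16
_LEVELS = 4
_BANDS = ("lh", "hl", "hh")


def fourier_feature_names() -> list[str]:
    return ([f"fourier.annulus.{i:02d}" for i in range(_N_ANNULI)]
            + [f"fourier.sector.{i:02d}" for i in range(_N_SECTORS)]
            + ["fourier.centroid_radius"])


def wavelet_feature_names() -> list[str]:
    names = []
    for lev in range(1, _LEVELS + 1):
        names += [f"wavelet.energy.{b}.L{lev}" for b in _BANDS]
        names += [f"wavelet.efrac.{b}.L{lev}" for b in _BANDS]
        names += [f"wavelet.entropy.{b}.L{lev}" for b in _BANDS]
    names.append("wavelet.approx_energy")
    return names


def _mean_filled_crop(image: MammogramImage) -> np.ndarray:
    rows = np.flatnonzero(image.mask.any(axis=1))
    cols = np.flatnonzero(image.mask.any(axis=0))
    crop = image.pixels[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    crop_mask = image.mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    if crop.shape[0] < 16 or crop.shape[1] < 16:
        raise ValueError(
            f"mask bounding box {crop.shape} smaller than 16x16: "
            "spectral features undefined")
    filled = crop.astype(float).copy()
    filled[~crop_mask] = crop[crop_mask].mean()
    return filled


def fourier_features(image: MammogramImage) -> dict[str, float]:
    """33 power-spectrum partition features."""
    filled = _mean_filled_crop(image)
    ac = filled - filled.mean()
    power = np.abs(np.fft.fft2(ac)) ** 2
    h, w = power.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.sqrt(fy ** 2 + fx ** 2)
    power[0, 0] = 0.0  # DC carries no texture information
    total = power.sum()
    out: dict[str, float] = {}
    if total <= 0:
        for name in fourier_feature_names():
            out[name] = 0.0
        return out
    edges = np.linspace(0.0, 0.5, _N_ANNULI + 1)
    for i in range(_N_ANNULI):
        sel = (radius > edges[i]) & (radius <= edges[i + 1])
        out[f"fourier.annulus.{i:02d}"] = float(power[sel].sum() / total)
    angle = np.mod(np.degrees(np.arctan2(fy, fx)), 180.0)
    sector = np.minimum((angle / (180.0 / _N_SECTORS)).astype(int),
                        _N_SECTORS - 1)
    nonzero = radius > 0
    for i in range(_N_SECTORS):
        sel = nonzero & (sector == i)
        out[f"fourier.sector.{i:02d}"] = float(power[sel].sum() / total)
    out["fourier.centroid_radius"] = float((radius * power).sum() / total)
    return out


def wavelet_features(image: MammogramImage) -> dict[str, float]:
    """37 sub-band energy features from a 4-level Daubechies-4 transform."""
    filled = _mean_filled_crop(image)
    with warnings.catch_warnings():
        # On small crops a 4-level transform exceeds the textbook maximum
        # decomposition depth; periodization keeps it well defined.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(filled, "db4", mode="periodization",
                               level=_LEVELS)
    approx = coeffs[0]
    details = coeffs[1:]            # coarsest-first: level 4 ... level 1
    energies: dict[tuple[int, str], float] = {}
    for depth, (ch, cv, cd) in enumerate(details):
        lev = _LEVELS - depth       # finest scale is level 1
        for band, c in zip(_BANDS, (ch, cv, cd)):
            energies[(lev, band)] = float((c ** 2).sum())
    approx_energy = float((approx ** 2).sum())
    total = approx_energy + sum(energies.values())
    # Filter-bank roundoff leaves ~1e-26 of energy in flat sub-bands; clamp
    # negligible detail energies so constant regions report exact zeros.
    tiny = 1e-12 * total
    energies = {k: (0.0 if e < tiny else e) for k, e in energies.items()}
    out: dict[str, float] = {}
    for lev in range(1, _LEVELS + 1):
        for band in _BANDS:
            out[f"wavelet.energy.{band}.L{lev}"] = energies[(lev, band)]
        for band in _BANDS:
            e = energies[(lev, band)]
            out[f"wavelet.efrac.{band}.L{lev}"] = e / total if total > 0 else 0.0
    for depth, (ch, cv, cd) in enumerate(details):
        lev = _LEVELS - depth
        for band, c in zip(_BANDS, (ch, cv, cd)):
            e = energies[(lev, band)]
            if e > 0:
                p = (c ** 2).ravel() / e
                p = p[p > 0]
                ent = float(-(p * np.log(p)).sum())
            else:
                ent = 0.0
            out[f"wavelet.entropy.{band}.L{lev}"] = ent
    out["wavelet.approx_energy"] = approx_energy
    return out


def spectral_features(image: MammogramImage) -> dict[str, float]:
    """70 spectral features: 33 Fourier + 37 wavelet."""
    out = fourier_features(image)
    out.update(wavelet_features(image))
    return out
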