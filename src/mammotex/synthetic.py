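"""Synthetic mammograms and patient cohorts.

The generator emulates the two inputs of the masking-prediction pipeline:

* textured grayscale "mammograms" whose percentage of dense (bright) pixels
  is controllable, built from a smoothed Gaussian random field inside a
  half-ellipse breast mask;
* patient cohorts whose covariate distributions match a hospital-based
  diagnostic mammography population and whose masking outcomes are drawn
  from the reference logistic risk model.

Everything is deterministic per seed, so the full pipeline is testable
without any image archive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import MammogramImage
from .masking import MaskingRiskModel, REFERENCE_MASKING_MODEL, MENO_LEVELS

__all__ = [
    "CohortParams",
    "REFERENCE_COHORT_PARAMS",
    "generate_mammogram",
    "generate_cohort",
    "breast_mask",
]

#: Default gray-level cut separating "dense" from "soft" tissue.
DENSITY_THRESHOLD = 128


def breast_mask(height: int, width: int) -> np.ndarray:
    """Half-ellipse breast outline anchored at the left image edge.

    The semi-axes are 0.45*height (vertical) and 0.8*width (horizontal), so
    the mask covers roughly 57% of the frame — large enough that every
    extractor must honor masking, small enough to leave real background.
    """
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    a = 0.45 * height
    b = 0.8 * width
    return ((rows - height / 2.0) / a) ** 2 + (cols / b) ** 2 <= 1.0


def generate_mammogram(height: int, width: int, target_pmd: float,
                       texture_scale: float = 8.0,
                       seed: int = 0) -> MammogramImage:
    """Generate a textured image with a prescribed percent density.

    White noise is smoothed with an isotropic Gaussian kernel of width
    ``texture_scale`` (pixels), giving a cloudy field with spatially
    correlated gray levels, then monotonically rescaled inside the mask so
    that the fraction of masked pixels at or above the density threshold
    (128) matches ``target_pmd`` to within one percentage point. Pixels
    outside the mask are 0.
    """
    if not 0.0 <= target_pmd <= 100.0:
        raise ValueError(f"target_pmd must lie in [0, 100], got {target_pmd}")
    if height < 32 or width < 32:
        raise ValueError("image must be at least 32x32 to host a breast mask")
    if texture_scale < 1:
        raise ValueError("texture_scale must be >= 1 pixel")
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal((height, width)),
                                    sigma=texture_scale, mode="reflect")
    mask = breast_mask(height, width)
    v = field[mask]
    lo, hi = float(v.min()), float(v.max())
    pixels = np.zeros((height, width), dtype=float)
    if hi - lo < 1e-12:
        # Degenerate constant field: place everything on one side of the cut.
        pixels[mask] = 200.0 if target_pmd >= 50.0 else 60.0
    elif target_pmd <= 0.0:
        pixels[mask] = (field[mask] - lo) / (hi - lo) * 127.0
    elif target_pmd >= 100.0:
        pixels[mask] = 128.0 + (field[mask] - lo) / (hi - lo) * 127.0
    else:
        # Piecewise-linear monotone map sending the (1 - p) quantile to the
        # density threshold: the >= 128 fraction equals target_pmd up to the
        # empirical-quantile granularity (far below one point here).
        q = float(np.quantile(v, 1.0 - target_pmd / 100.0))
        if q - lo < 1e-12:
            pixels[mask] = 128.0 + (field[mask] - q) / (hi - q) * 127.0
        elif hi - q < 1e-12:
            pixels[mask] = (field[mask] - lo) / (q - lo) * 127.4
        else:
            f = field[mask]
            low = (f - lo) / (q - lo) * 127.4
            high = 128.0 + (f - q) / (hi - q) * 127.0
            pixels[mask] = np.where(f < q, low, high)
    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    pixels[~mask] = 0
    return MammogramImage(pixels=pixels, mask=mask)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Marginal covariate distribution of a simulated cohort.

    Continuous covariates are normal (PMD truncated to [0, 100] by
    resampling); surgery and imaging technique are Bernoulli; the
    menopausal/HRT factor is categorical with the three probabilities
    summing to 1.
    """

    n: int
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    pmd_mean: float
    pmd_sd: float
    p_surgery: float
    p_premeno: float
    p_postmeno_nohrt: float
    p_postmeno_hrt: float
    p_digital: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name in ("p_surgery", "p_premeno", "p_postmeno_nohrt",
                     "p_postmeno_hrt", "p_digital"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        total = self.p_premeno + self.p_postmeno_nohrt + self.p_postmeno_hrt
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"menopausal/HRT probabilities sum to {total}, expected 1")
        for name in ("age_sd", "bmi_sd", "pmd_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _mix(w1: float, m1: float, s1: float, w2: float, m2: float,
         s2: float) -> tuple[float, float]:
    """Mean and SD of a two-component mixture of normals."""
    m = w1 * m1 + w2 * m2
    var = w1 * (s1 ** 2 + (m1 - m) ** 2) + w2 * (s2 ** 2 + (m2 - m) ** 2)
    return m, float(np.sqrt(var))

# Group summaries of the reference diagnostic mammography cohort
# (1227 patients without / 107 with a masked tumor), combined into
# full-cohort marginals with the observed 1227:107 weights.
_W0, _W1 = 1227 / 1334, 107 / 1334
_AGE = _mix(_W0, 60.2, 12.5, _W1, 52.5, 12.1)
_BMI = _mix(_W0, 26.4, 4.7, _W1, 23.7, 3.5)
_PMD = _mix(_W0, 34.5, 18.3, _W1, 51.3, 20.5)

#: Covariate marginals of the reference cohort (n = 1334): age ~59.6 (12.6),
#: BMI ~26.2 (4.7), PMD ~35.8 (19.0), 13.1% prior surgery, menopausal mix
#: 23.6/56.1/20.2%, 38.8% digital technique.
REFERENCE_COHORT_PARAMS = CohortParams(
    n=1334,
    age_mean=_AGE[0], age_sd=_AGE[1],
    bmi_mean=_BMI[0], bmi_sd=_BMI[1],
    pmd_mean=_PMD[0], pmd_sd=_PMD[1],
    p_surgery=(156 + 19) / 1334,
    p_premeno=(269 + 46) / 1334,
    p_postmeno_nohrt=(721 + 28) / 1334,
    p_postmeno_hrt=(246 + 24) / 1334,
    p_digital=(475 + 43) / 1334,
)


def _truncated_normal(rng: np.random.Generator, n: int, mean: float,
                      sd: float, lo: float, hi: float) -> np.ndarray:
    """Normal draws truncated to [lo, hi] by resampling."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(params: CohortParams,
                    coefficients: MaskingRiskModel = REFERENCE_MASKING_MODEL,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate a cohort with masking outcomes from a logistic truth.

    Covariates are drawn independently from the marginals in ``params``
    (no correlation structure is imposed), then the masking indicator is
    Bernoulli with probability ``exp(z)/(1+exp(z))`` where z is the linear
    predictor of ``coefficients`` evaluated at the observed PMD.
    """
    if seed is not None:
        params = replace(params, seed=seed)
    rng = np.random.default_rng(params.seed)
    n = params.n
    columns = ["patient_id", "age", "bmi", "surgery", "meno_hrt",
               "technique", "pmd_observed", "masked"]
    if n == 0:
        return pd.DataFrame({c: [] for c in columns})
    meno = rng.choice(np.array(MENO_LEVELS),
                      p=[params.p_premeno, params.p_postmeno_nohrt,
                         params.p_postmeno_hrt],
                      size=n)
    cohort = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "age": rng.normal(params.age_mean, params.age_sd, size=n),
        "bmi": rng.normal(params.bmi_mean, params.bmi_sd, size=n),
        "surgery": rng.binomial(1, params.p_surgery, size=n),
        "meno_hrt": meno,
        "technique": np.where(rng.random(n) < params.p_digital,
                              "digital", "analog"),
        "pmd_observed": _truncated_normal(rng, n, params.pmd_mean,
                                          params.pmd_sd, 0.0, 100.0),
    })
    risk = coefficients.predict_risk(
        cohort, pmd_values=cohort["pmd_observed"].to_numpy())
    cohort["masked"] = rng.binomial(1, risk)
    return cohort[columns]
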