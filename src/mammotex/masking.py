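"""Logistic regression model for masking (mammography failure).

Masking is the event that an invasive tumor is visible on ultrasound but
assigned an unsuspicious (BI-RADS 1/2) mammogram. The risk model is an
ordinary logistic regression on the clinical predictors

    age (years), BMI (kg/m^2), previous breast surgery (yes/no),
    menopausal/HRT status (premenopausal, postmenopausal without HRT,
    postmenopausal with HRT), imaging technique (analog/digital),

plus one percentage-mammographic-density (PMD) variable — observed PMD or a
PMD value predicted from texture features. The linear predictor is
``z = b0 + sum(b_j x_j)`` and the masking risk is ``exp(z)/(1+exp(z))``.
Reference categories (no surgery, premenopausal, analog) carry coefficient 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MaskingRiskModel",
    "REFERENCE_MASKING_MODEL",
    "fit_masking_model",
    "predict_masking_risk",
    "MENO_LEVELS",
]

#: Valid levels of the combined menopausal/HRT factor, reference first.
MENO_LEVELS = ("premenopausal", "postmeno_no_hrt", "postmeno_hrt")

_CLINICAL_TERMS = ("age", "bmi", "surgery", "postmeno_no_hrt",
                   "postmeno_hrt", "digital")


@dataclass(frozen=True)
class MaskingRiskModel:
    """Coefficients (log-odds scale) of the masking logistic model.

    ``pmd`` is the slope per percentage point of mammographic density; it is
    ``None`` for the clinical-only model and absent together with all slopes
    for the null (intercept-only) model.
    """

    intercept: float
    age: float = 0.0
    bmi: float = 0.0
    surgery: float = 0.0
    postmeno_no_hrt: float = 0.0
    postmeno_hrt: float = 0.0
    digital: float = 0.0
    pmd: float | None = None
    standard_errors: dict[str, float] = field(default_factory=dict)

    def linear_predictor(self, cohort: pd.DataFrame,
                         pmd_values: np.ndarray | None = None) -> np.ndarray:
        """z for every cohort row; ``pmd_values`` overrides any PMD column."""
        X = _design_matrix(cohort)
        z = (self.intercept
             + self.age * X["age"] + self.bmi * X["bmi"]
             + self.surgery * X["surgery"]
             + self.postmeno_no_hrt * X["postmeno_no_hrt"]
             + self.postmeno_hrt * X["postmeno_hrt"]
             + self.digital * X["digital"])
        if self.pmd is not None:
            if pmd_values is None:
                raise ValueError("model includes PMD but no PMD values given")
            z = z + self.pmd * np.asarray(pmd_values, dtype=float)
        return np.asarray(z, dtype=float)

    def predict_risk(self, cohort: pd.DataFrame,
                     pmd_values: np.ndarray | None = None) -> np.ndarray:
        z = self.linear_predictor(cohort, pmd_values)
        return 1.0 / (1.0 + np.exp(-z))


#: Coefficients (and standard errors) of the reference masking model from a
#: hospital-based diagnostic mammography cohort (n = 1334, 8% masking
#: prevalence), with PMD entering as a single linear slope. Used as the
#: generative truth of the synthetic cohort generator.
REFERENCE_MASKING_MODEL = MaskingRiskModel(
    intercept=-0.906,
    age=-0.018,
    bmi=-0.080,
    surgery=0.502,
    postmeno_no_hrt=-0.530,
    postmeno_hrt=0.208,
    digital=0.416,
    pmd=0.032,
    standard_errors={
        "intercept": 1.308, "age": 0.014, "bmi": 0.033, "surgery": 0.286,
        "postmeno_no_hrt": 0.357, "postmeno_hrt": 0.355, "digital": 0.223,
        "pmd": 0.009,
    },
)


def _design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded clinical design matrix (reference levels dropped)."""
    meno = cohort["meno_hrt"]
    unknown = set(meno.unique()) - set(MENO_LEVELS)
    if unknown:
        raise ValueError(f"unknown menopausal/HRT level(s): {sorted(unknown)}")
    technique = cohort["technique"]
    bad = set(technique.unique()) - {"analog", "digital"}
    if bad:
        raise ValueError(f"unknown imaging technique level(s): {sorted(bad)}")
    return pd.DataFrame({
        "age": cohort["age"].astype(float),
        "bmi": cohort["bmi"].astype(float),
        "surgery": cohort["surgery"].astype(float),
        "postmeno_no_hrt": (meno == "postmeno_no_hrt").astype(float),
        "postmeno_hrt": (meno == "postmeno_hrt").astype(float),
        "digital": (technique == "digital").astype(float),
    }, index=cohort.index)


def fit_masking_model(cohort: pd.DataFrame,
                      pmd_column: str | None = "pmd_observed",
                      include_clinical: bool = True) -> MaskingRiskModel:
    """Maximum-likelihood logistic fit of masking status.

    Parameters
    ----------
    cohort
        Table with columns ``age, bmi, surgery, meno_hrt, technique, masked``
        plus the PMD column if requested. Both outcome classes must occur.
    pmd_column
        Column holding the PMD variable (observed or predicted); ``None``
        fits the clinical-only model.
    include_clinical
        ``False`` (with ``pmd_column=None``) fits the null, intercept-only
        model, whose predictions are the training prevalence.

    Returns the fitted coefficients with standard errors from the observed
    information matrix (Newton iterations, score tolerance 1e-8).
    """
    y = cohort["masked"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("masking outcome has a single class; cannot fit")
    cols: list[str] = []
    parts = [pd.Series(1.0, index=cohort.index, name="intercept")]
    if include_clinical:
        X = _design_matrix(cohort)
        parts.append(X)
        cols.extend(_CLINICAL_TERMS)
    if pmd_column is not None:
        parts.append(cohort[pmd_column].astype(float).rename("pmd"))
        cols.append("pmd")
    design = pd.concat(parts, axis=1)
    try:
        with warnings.catch_warnings():
            # Newton occasionally stops at maxiter on near-separated small
            # folds; the final iterate is still the usable MLE candidate.
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(method="newton", maxiter=100,
                                          tol=1e-8, disp=0)
    except Exception as exc:  # pragma: no cover - separation is data-specific
        raise ValueError(f"logistic fit failed (separation?): {exc}") from exc
    params = dict(zip(design.columns, res.params))
    ses = dict(zip(design.columns, res.bse))
    return MaskingRiskModel(
        intercept=params["intercept"],
        age=params.get("age", 0.0),
        bmi=params.get("bmi", 0.0),
        surgery=params.get("surgery", 0.0),
        postmeno_no_hrt=params.get("postmeno_no_hrt", 0.0),
        postmeno_hrt=params.get("postmeno_hrt", 0.0),
        digital=params.get("digital", 0.0),
        pmd=params.get("pmd") if pmd_column is not None else None,
        standard_errors=ses,
    )


def predict_masking_risk(model: MaskingRiskModel, cohort: pd.DataFrame,
                         pmd_values: np.ndarray | None = None) -> np.ndarray:
    """Per-patient masking risk ``exp(z)/(1+exp(z))`` in (0, 1)."""
    return model.predict_risk(cohort, pmd_values)
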