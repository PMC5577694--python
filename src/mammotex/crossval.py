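"""Repeated double (nested) cross-validation of masking prediction.

The outer loop splits the cohort into 3 folds (stratified by masking
status, repeated 100 times by default): each fold in turn is the validation
third, the other two thirds are training data. On the training part only,
the tuning parameter of each PMD regression technique is chosen by inner
10-fold cross-validation (out-of-bag error for the forest), the PMD model
is fitted and applied to produce predicted PMD on both parts, and all
masking logistic models are fitted:

* ``null`` — intercept only,
* ``clinical`` — clinical predictors without PMD,
* ``predicted_<method>`` — clinical predictors + predicted PMD,
* ``observed`` — clinical predictors + observed PMD.

On the held-out third each model is scored by Brier MSE, AUC, continuous
NRI against the clinical model, and discovery rates at the configured
cut-offs. No validation-fold datum influences any fitting or tuning step.
Aggregation is the arithmetic mean/SD over all repetition x fold records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import pmd as pmd_mod
from .masking import fit_masking_model
from .metrics import auc, brier_mse, continuous_nri, discovery_rates

__all__ = ["CVConfig", "EvaluationReport", "repeated_double_cv"]


@dataclass(frozen=True)
class CVConfig:
    """Shape of the repeated double cross-validation."""

    n_repetitions: int = 100
    outer_folds: int = 3
    inner_folds: int = 10
    seed: int = 0
    methods: tuple[str, ...] = ("boosting",)
    cutoffs: tuple[float, ...] = (5, 10, 12, 15, 20)
    grids: dict[str, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        unknown = set(self.methods) - set(pmd_mod.METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        for c in self.cutoffs:
            if not 0 < c < 100:
                raise ValueError("cutoffs must lie in (0, 100)")


@dataclass
class EvaluationReport:
    """Per-record metrics and their aggregation.

    ``records`` has one row per (repetition, fold, model) with columns
    ``mse``, ``auc``, ``nri``, ``up_events``, ``down_nonevents`` (NRI fields
    are NaN for the null and clinical models, which are their own
    reference); ``discovery`` one row per (repetition, fold, model, cutoff).
    """

    records: pd.DataFrame
    discovery: pd.DataFrame
    config: CVConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def summary(self) -> pd.DataFrame:
        """Mean and SD of each metric over all repetition x fold records."""
        agg = self.records.groupby("model")[
            ["mse", "auc", "nri", "up_events", "down_nonevents"]
        ].agg(["mean", "std"])
        order = [m for m in _MODEL_ORDER if m in agg.index]
        extra = [m for m in agg.index if m not in order]
        return agg.loc[order + extra]

    def discovery_summary(self) -> pd.DataFrame:
        """Mean frequency-above and discovery rate per model and cut-off."""
        return (self.discovery
                .groupby(["model", "cutoff"])[
                    ["frequency_above", "discovery_rate"]]
                .mean().reset_index())


_MODEL_ORDER = ("null", "clinical", "predicted_univariate",
                "predicted_lasso", "predicted_boosting", "predicted_forest",
                "observed")


def _rep_seed(seed: int, rep: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence(entropy=(seed, rep, salt))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def repeated_double_cv(cohort: pd.DataFrame,
                       features: pd.DataFrame | None,
                       config: CVConfig) -> EvaluationReport:
    """Run the full repeated double cross-validation.

    ``cohort`` and ``features`` are joined on ``patient_id``; ``features``
    may be ``None`` when no PMD regression technique is requested (the
    null, clinical and observed-PMD models need no texture features).
    """
    cohort = cohort.reset_index(drop=True)
    if config.methods and features is None:
        raise ValueError("texture features required for PMD methods")
    if features is not None:
        features = (features.set_index("patient_id")
                    .loc[cohort["patient_id"]].reset_index(drop=True))
    y_mask = cohort["masked"].to_numpy(dtype=int)
    if len(np.unique(y_mask)) < 2:
        raise ValueError("cohort must contain both masking classes")
    feat_cols = ([c for c in features.columns if c != "patient_id"]
                 if features is not None else [])

    records: list[dict] = []
    disc_rows: list[dict] = []
    for rep in range(config.n_repetitions):
        skf = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                              random_state=_rep_seed(config.seed, rep))
        for fold, (tr, va) in enumerate(skf.split(cohort, y_mask)):
            ctr, cva = cohort.iloc[tr], cohort.iloc[va]
            pmd_obs_tr = ctr["pmd_observed"].to_numpy(dtype=float)

            # --- PMD regression models, tuned and fitted on training only
            val_pmd: dict[str, np.ndarray] = {}
            train_pmd: dict[str, np.ndarray] = {}
            for method in config.methods:
                Xtr = features.iloc[tr][feat_cols]
                Xva = features.iloc[va][feat_cols]
                grid = (config.grids or {}).get(method)
                model = pmd_mod.fit_pmd_model(
                    Xtr, pmd_obs_tr, method, grid=grid,
                    folds=config.inner_folds,
                    seed=_rep_seed(config.seed, rep, salt=1 + fold))
                train_pmd[method] = pmd_mod.predict_pmd(model, Xtr)
                val_pmd[method] = pmd_mod.predict_pmd(model, Xva)

            # --- masking logistic models on the training two-thirds
            fits = {}
            fits["null"] = fit_masking_model(ctr, pmd_column=None,
                                             include_clinical=False)
            fits["clinical"] = fit_masking_model(ctr, pmd_column=None)
            for method in config.methods:
                aug = ctr.assign(_pmd_pred=train_pmd[method])
                fits[f"predicted_{method}"] = fit_masking_model(
                    aug, pmd_column="_pmd_pred")
            fits["observed"] = fit_masking_model(ctr,
                                                 pmd_column="pmd_observed")

            # --- scoring on the held-out third
            status = cva["masked"].to_numpy(dtype=int)
            risks: dict[str, np.ndarray] = {}
            for name, fit in fits.items():
                if name == "null" or name == "clinical":
                    pmd_vals = None
                elif name == "observed":
                    pmd_vals = cva["pmd_observed"].to_numpy(dtype=float)
                else:
                    pmd_vals = val_pmd[name.removeprefix("predicted_")]
                risks[name] = fit.predict_risk(cva, pmd_vals)
            for name, risk in risks.items():
                rec = {"repetition": rep, "fold": fold, "model": name,
                       "mse": brier_mse(status, risk),
                       "auc": auc(status, risk),
                       "nri": np.nan, "up_events": np.nan,
                       "down_nonevents": np.nan}
                if name not in ("null", "clinical"):
                    nri, up, down = continuous_nri(status, risk,
                                                   risks["clinical"])
                    rec.update(nri=nri, up_events=up, down_nonevents=down)
                records.append(rec)
                if name != "null":
                    table = discovery_rates(status, risk, config.cutoffs)
                    for row in table.itertuples(index=False):
                        disc_rows.append({
                            "repetition": rep, "fold": fold, "model": name,
                            "cutoff": row.cutoff,
                            "frequency_above": row.frequency_above,
                            "discovery_rate": row.discovery_rate})
    return EvaluationReport(records=pd.DataFrame(records),
                            discovery=pd.DataFrame(disc_rows),
                            config=config)
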