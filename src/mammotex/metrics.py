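"""Performance metrics for masking-risk models.

* Brier-type MSE between the binary masking status and the predicted risk;
* AUC as the tie-corrected Mann-Whitney statistic (a constant predictor —
  the null model — scores exactly 0.5);
* continuous net reclassification improvement (NRI) of a new risk model
  against an old one, with its upward/downward components;
* discovery rates: among truly masked tumors, the proportion assigned a
  risk above a cut-off, together with the fraction of the whole population
  above that cut-off.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["brier_mse", "auc", "roc_points", "continuous_nri",
           "discovery_rates"]


def _check(status: np.ndarray, risk: np.ndarray) -> tuple[np.ndarray,
                                                          np.ndarray]:
    status = np.asarray(status, dtype=float)
    risk = np.asarray(risk, dtype=float)
    if status.size == 0:
        raise ValueError("empty input")
    if status.shape != risk.shape:
        raise ValueError("status and risk must have equal length")
    return status, risk


def brier_mse(status: np.ndarray, risk: np.ndarray) -> float:
    """Mean squared difference between 0/1 status and predicted risk."""
    status, risk = _check(status, risk)
    if risk.min() < 0 or risk.max() > 1:
        raise ValueError("risks must lie in [0, 1]")
    return float(np.mean((status - risk) ** 2))


def auc(status: np.ndarray, risk: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2.

    ``[#(risk_event > risk_nonevent) + 0.5 * #ties] / (n1 * n0)`` computed
    via midranks. Requires both outcome classes.
    """
    status, risk = _check(status, risk)
    n1 = int(status.sum())
    n0 = status.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both outcome classes")
    ranks = rankdata(risk)
    return float((ranks[status == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(status: np.ndarray, risk: np.ndarray) -> pd.DataFrame:
    """ROC curve as (fpr, tpr) points, monotone in both coordinates."""
    status, risk = _check(status, risk)
    fpr, tpr, _ = _sk_roc_curve(status, risk)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def continuous_nri(status: np.ndarray, risk_new: np.ndarray,
                   risk_old: np.ndarray) -> tuple[float, float, float]:
    """Continuous NRI of ``risk_new`` versus ``risk_old``.

    An event counts as correctly reclassified if the new model raises its
    risk, a nonevent if the new model lowers it; ties count toward neither
    direction. Returns ``(nri, up_events, down_nonevents)`` where

        nri = [P(up|event) - P(down|event)]
            + [P(down|nonevent) - P(up|nonevent)]      in [-2, 2].
    """
    status, risk_new = _check(status, risk_new)
    risk_old = np.asarray(risk_old, dtype=float)
    events = status == 1
    if not events.any() or events.all():
        raise ValueError("NRI needs both outcome classes")
    up = risk_new > risk_old
    down = risk_new < risk_old
    up_events = float(up[events].mean())
    down_events = float(down[events].mean())
    up_non = float(up[~events].mean())
    down_non = float(down[~events].mean())
    nri = (up_events - down_events) + (down_non - up_non)
    return nri, up_events, down_non


def discovery_rates(status: np.ndarray, risk: np.ndarray,
                    cutoffs: tuple[float, ...] = (5, 10, 12, 15, 20)
                    ) -> pd.DataFrame:
    """High-risk frequency and discovery rate at each percent cut-off.

    A patient is "high risk" when risk > cutoff/100. ``frequency_above`` is
    the high-risk share of the whole population; ``discovery_rate`` the
    high-risk share among truly masked tumors. Both returned in percent.
    """
    status, risk = _check(status, risk)
    if risk.min() < 0 or risk.max() > 1:
        raise ValueError("risks must lie in [0, 1]")
    if not (status == 1).any():
        raise ValueError("discovery rate undefined without events")
    rows = []
    events = status == 1
    for c in cutoffs:
        high = risk > c / 100.0
        rows.append({
            "cutoff": float(c),
            "frequency_above": 100.0 * float(high.mean()),
            "discovery_rate": 100.0 * float(high[events].mean()),
        })
    return pd.DataFrame(rows)
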