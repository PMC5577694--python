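"""Outcome-blind feature preselection.

Before any model building, the feature set is thinned in two steps:
features with extreme sample skewness are dropped (an automated stand-in
for visual box-plot screening), and the remainder is pruned for redundancy
— features are put in random order and any feature with an absolute
Spearman correlation above the cutoff with a higher-ranked retained feature
is excluded. A small set of basic intensity features (central moments and
histogram bins) is always kept. The procedure uses no outcome information
and is run once on the full table, never inside cross-validation folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import BASIC_FEATURES

__all__ = ["PreselectionConfig", "preselect_features"]


@dataclass(frozen=True)
class PreselectionConfig:
    """Knobs of the preselection step.

    ``corr_cutoff`` is the |Spearman rho| above which a feature is redundant
    (default 0.98); ``skew_threshold`` the absolute sample skewness beyond
    which a feature is considered pathologically skewed (default 10);
    ``forced_keep`` names accepted without preselection (default: the basic
    intensity features present in the table); ``seed`` fixes the random
    ranking.
    """

    skew_threshold: float = 10.0
    corr_cutoff: float = 0.98
    forced_keep: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.corr_cutoff <= 1.0:
            raise ValueError("corr_cutoff must lie in (0, 1]")


def preselect_features(table: pd.DataFrame,
                       config: PreselectionConfig = PreselectionConfig()
                       ) -> list[str]:
    """Retained feature names, in the table's column order.

    ``table`` holds one column per feature (a ``patient_id`` column, if
    present, is ignored). Constant features have undefined Spearman
    correlation; they are treated as uncorrelated with everything and are
    only subject to the skewness rule.
    """
    columns = [c for c in table.columns if c != "patient_id"]
    if len(table) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    X = table[columns].to_numpy(dtype=float)
    if config.forced_keep is None:
        forced = [c for c in BASIC_FEATURES if c in columns]
    else:
        unknown = set(config.forced_keep) - set(columns)
        if unknown:
            raise ValueError(f"forced_keep not in table: {sorted(unknown)}")
        forced = list(config.forced_keep)

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant columns
        skew = stats.skew(X, axis=0, bias=True)
    skew = np.nan_to_num(skew, nan=0.0)
    candidates = [c for c, s in zip(columns, skew)
                  if abs(s) <= config.skew_threshold]

    rng = np.random.default_rng(config.seed)
    order = [candidates[i] for i in rng.permutation(len(candidates))]

    # Spearman = Pearson on ranks; constant columns get rho 0 by zeroing
    # their zero-variance rank vectors.
    ranks = stats.rankdata(X, axis=0)
    ranks = ranks - ranks.mean(axis=0)
    norms = np.sqrt((ranks ** 2).sum(axis=0))
    col_index = {c: i for i, c in enumerate(columns)}
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norms > 0, ranks / np.where(norms > 0, norms, 1.0),
                        0.0)

    kept: list[str] = []
    for name in order:
        u = unit[:, col_index[name]]
        redundant = any(
            abs(float(u @ unit[:, col_index[k]])) > config.corr_cutoff
            for k in kept)
        if not redundant:
            kept.append(name)
    retained = set(kept) | set(forced)
    return [c for c in columns if c in retained]
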