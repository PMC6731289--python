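"""Environmental-parameter screens: Spearman correlation and VIF collinearity.

Taxon or function abundances (at a chosen aggregation level, floored at a
minimum mean relative abundance of 0.1%) are screened against per-plant
process parameters (temperature, pH, VFA, substrate fractions, C/N) with
Spearman's rho at p <= 0.01.  Metadata collinearity is screened with the
variance inflation factor VIF_j = 1 / (1 - R^2_j); variables with VIF >= 10
are flagged and, in iterative mode, removed highest-first.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .abundance import check_abundance_frame, plant_means, sample_plants

logger = logging.getLogger(__name__)

SPEARMAN_ALPHA = 0.01
ABUNDANCE_FLOOR = 0.1
VIF_THRESHOLD = 10.0


def abundance_floor(X: pd.DataFrame, min_mean: float = ABUNDANCE_FLOOR) -> pd.DataFrame:
    """Keep features whose mean relative abundance across samples is >= ``min_mean``
    (percent; the threshold is inclusive)."""
    check_abundance_frame(X)
    return X.loc[:, X.mean(axis=0) >= min_mean]


def spearman_screen(
    X: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = SPEARMAN_ALPHA,
    mode: str = "per_replicate",
) -> pd.DataFrame:
    """Spearman rho and p for every (feature, metadata variable) combination.

    Replicates inherit their plant's metadata row.  ``mode='per_plant'``
    correlates plant means instead of all replicate samples.  Constant features
    or variables yield undefined rho and are excluded (logged).  Returns a tidy
    frame with columns feature, variable, rho, p, significant (p <= alpha).
    """
    if mode == "per_plant":
        X = plant_means(X, renormalize=False)
        meta_rows = metadata.loc[X.index]
    elif mode == "per_replicate":
        meta_rows = metadata.loc[sample_plants(X)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    records = []
    n_skipped = 0
    for var in metadata.columns:
        y = pd.to_numeric(meta_rows[var], errors="raise").to_numpy(dtype=float)
        if np.ptp(y) == 0:
            n_skipped += X.shape[1]
            continue
        for feat in X.columns:
            x = X[feat].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                n_skipped += 1
                continue
            rho, p = stats.spearmanr(x, y)
            records.append({"feature": feat, "variable": var,
                            "rho": float(rho), "p": float(p),
                            "significant": bool(p <= alpha)})
    if n_skipped:
        logger.info("spearman_screen: excluded %d constant combination(s)", n_skipped)
    return pd.DataFrame(records, columns=["feature", "variable", "rho", "p", "significant"])


def _vif_values(meta: pd.DataFrame) -> pd.Series:
    """VIF of each column from least-squares regression on the others."""
    Z = meta.to_numpy(dtype=float)
    n, k = Z.shape
    out = {}
    for j, col in enumerate(meta.columns):
        y = Z[:, j]
        others = np.column_stack([np.ones(n), np.delete(Z, j, axis=1)])
        resid = y - others @ np.linalg.lstsq(others, y, rcond=None)[0]
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_res = float((resid**2).sum())
        if ss_tot == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def vif_screen(
    metadata: pd.DataFrame,
    threshold: float = VIF_THRESHOLD,
    iterative: bool = True,
) -> tuple[list, pd.DataFrame]:
    """Collinearity screen; returns (kept variables, per-round VIF report).

    In iterative mode the variable with the highest VIF >= ``threshold`` is
    removed and VIFs are recomputed until all remaining VIFs are below the
    threshold.  Perfectly collinear variables get infinite VIF and are removed
    first.
    """
    meta = metadata.apply(pd.to_numeric, errors="raise")
    if meta.shape[1] < 2:
        raise ValueError("need at least two numeric variables for a VIF screen")
    if meta.shape[0] <= meta.shape[1]:
        raise ValueError("need more observations than variables for the VIF regressions")
    report_rows = []
    kept = list(meta.columns)
    round_no = 0
    while True:
        vifs = _vif_values(meta[kept])
        for var, v in vifs.items():
            report_rows.append({"round": round_no, "variable": var, "vif": float(v),
                                "flagged": bool(v >= threshold)})
        worst = vifs.idxmax()
        if vifs[worst] < threshold or not iterative:
            break
        logger.info("vif_screen: removing %r (VIF = %.3g)", worst, vifs[worst])
        kept.remove(worst)
        round_no += 1
        if len(kept) < 2:
            break
    return kept, pd.DataFrame(report_rows, columns=["round", "variable", "vif", "flagged"])


class SpearmanScreen(BaseEstimator):
    """Estimator form of the abundance/metadata Spearman screen.

    ``fit(X, metadata)`` applies the abundance floor then the screen; results
    land in ``records_`` (tidy frame) and ``significant_`` (records at
    p <= alpha).
    """

    def __init__(self, alpha: float = SPEARMAN_ALPHA,
                 min_mean: float = ABUNDANCE_FLOOR, mode: str = "per_replicate"):
        self.alpha = alpha
        self.min_mean = min_mean
        self.mode = mode

    def fit(self, X: pd.DataFrame, metadata: pd.DataFrame):
        floored = abundance_floor(X, min_mean=self.min_mean)
        self.n_features_in_ = X.shape[1]
        self.n_features_screened_ = floored.shape[1]
        self.records_ = spearman_screen(floored, metadata,
                                        alpha=self.alpha, mode=self.mode)
        self.significant_ = self.records_[self.records_["significant"]]
        return self
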