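"""Inverse probability of treatment weighting and covariate balance.

Propensity scores come from a logistic model of arm assignment on the seven
pre-specified baseline covariates (age, sex, plasma EBV DNA dichotomized at
2000 copies/ml, cervical nodal necrosis, primary tumor volume, N stage and
T stage; the stage categories enter as dummy indicators). Weights are
stabilized ATE weights with optional truncation of extreme propensity scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = [
    "age", "sex", "pebv_dna", "nodal_necrosis", "tumor_volume_ml",
    "n_stage", "t_stage",
]


def design_matrix(
    table: pd.DataFrame, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Covariate design matrix: continuous as is, stages as dummies,
    pEBV DNA as the >= 2000 copies/ml indicator used throughout."""
    covs = covariates or DEFAULT_COVARIATES
    cols = {}
    for c in covs:
        if c == "pebv_dna":
            cols["pebv_high"] = (table["pebv_dna"] >= 2000.0).astype(float)
        elif c in ("t_stage", "n_stage"):
            series = table[c].astype(int)
            for level in sorted(series.unique())[1:]:  # reference = lowest
                cols[f"{c}_{level}"] = (series == level).astype(float)
        else:
            cols[c] = table[c].astype(float)
    return pd.DataFrame(cols, index=table.index)


def fit_propensity(
    table: pd.DataFrame, covariates: list[str] | None = None
) -> np.ndarray:
    """Propensity e(x) = P(arm = 1 | x) from a logistic regression."""
    arm = table["arm"].to_numpy(dtype=float)
    if len(np.unique(arm)) < 2:
        raise ValueError("both treatment arms must be present")
    X = design_matrix(table, covariates)
    if X.isna().any().any():
        raise ValueError("missing covariate values")
    Xc = sm.add_constant(X.to_numpy(), has_constant="add")
    try:
        res = sm.Logit(arm, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(f"propensity model failed to fit: {exc}") from exc
    scores = np.asarray(res.predict(Xc), dtype=float)
    if np.any(scores <= 0) or np.any(scores >= 1):
        raise ValueError(
            "propensity scores collapsed to 0/1 — perfect separation "
            "between the arms on the supplied covariates"
        )
    return scores


def compute_weights(
    scores: np.ndarray,
    arm: np.ndarray,
    stabilized: bool = True,
    truncation: tuple[float, float] | None = (0.01, 0.99),
) -> np.ndarray:
    """Stabilized ATE weights T/e + (1-T)/(1-e).

    With stabilization each term is multiplied by the marginal arm
    probability, so weights average ~1. Scores outside the truncation
    quantiles are clipped (count logged).
    """
    scores = np.asarray(scores, dtype=float)
    arm = np.asarray(arm, dtype=int)
    if np.any(scores <= 0) or np.any(scores >= 1):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    if truncation is not None:
        lo, hi = np.quantile(scores, truncation)
        n_out = int(((scores < lo) | (scores > hi)).sum())
        if n_out:
            log.info("truncated %d propensity score(s) to [%.4f, %.4f]", n_out, lo, hi)
        scores = np.clip(scores, lo, hi)
    p1 = arm.mean()
    w = np.where(arm == 1, 1.0 / scores, 1.0 / (1.0 - scores))
    if stabilized:
        w = np.where(arm == 1, p1, 1.0 - p1) * w
    return w


def _smd_continuous(x: np.ndarray, arm: np.ndarray, w: np.ndarray) -> float:
    def moments(mask):
        ww = w[mask]
        xx = x[mask]
        m = np.average(xx, weights=ww)
        v = np.average((xx - m) ** 2, weights=ww)
        return m, v

    m1, v1 = moments(arm == 1)
    m0, v0 = moments(arm == 0)
    pooled = (v1 + v0) / 2.0
    if pooled == 0:
        return 0.0 if m1 == m0 else np.inf
    return abs(m1 - m0) / np.sqrt(pooled)


def _smd_binary(x: np.ndarray, arm: np.ndarray, w: np.ndarray) -> float:
    p1 = np.average(x[arm == 1], weights=w[arm == 1])
    p0 = np.average(x[arm == 0], weights=w[arm == 0])
    pooled = (p1 * (1 - p1) + p0 * (1 - p0)) / 2.0
    if pooled == 0:
        return 0.0 if p1 == p0 else np.inf
    return abs(p1 - p0) / np.sqrt(pooled)


@dataclass
class BalanceReport:
    table: pd.DataFrame  # per covariate: smd_before, smd_after
    weighted_n: dict  # arm -> weighted size

    @property
    def max_smd_after(self) -> float:
        return float(self.table["smd_after"].max())


def balance_report(
    table: pd.DataFrame,
    weights: np.ndarray,
    covariates: list[str] | None = None,
) -> BalanceReport:
    """Standardized mean differences before and after weighting."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(table):
        raise ValueError("weights must align with cohort rows")
    arm = table["arm"].to_numpy(dtype=int)
    X = design_matrix(table, covariates)
    ones = np.ones(len(table))
    rows = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        is_binary = set(np.unique(x)) <= {0.0, 1.0}
        fn = _smd_binary if is_binary else _smd_continuous
        rows[col] = {
            "smd_before": fn(x, arm, ones),
            "smd_after": fn(x, arm, weights),
        }
    weighted_n = {
        1: float(weights[arm == 1].sum()),
        0: float(weights[arm == 0].sum()),
    }
    if min(weighted_n.values()) <= 0:
        raise ValueError("weighted group size must be positive")
    return BalanceReport(table=pd.DataFrame(rows).T, weighted_n=weighted_n)
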