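"""Feature reproducibility screening via the intraclass correlation.

The ICC form is ICC(2,1): two-way random effects, absolute agreement, single
measurement (Shrout & Fleiss), computed from the two-way ANOVA decomposition.
Features are retained only when BOTH the intra-observer and inter-observer
ICC reach the threshold (0.8 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def icc(matrix: np.ndarray) -> float:
    """ICC(2,1) of an n_subjects x k_raters ratings matrix."""
    return float(icc_stack(np.asarray(matrix, dtype=float)[None, :, :])[0])


def icc_stack(stack: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) over a (features, subjects, raters) stack."""
    y = np.asarray(stack, dtype=float)
    if y.ndim != 3:
        raise ValueError("expected a (features, subjects, raters) array")
    _, n, k = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if k < 2:
        raise ValueError("need at least 2 raters")
    if not np.all(np.isfinite(y)):
        raise ValueError("ratings must be finite (no missing entries)")

    grand = y.mean(axis=(1, 2), keepdims=True)
    subj = y.mean(axis=2, keepdims=True)
    rater = y.mean(axis=1, keepdims=True)

    msr = k * ((subj - grand) ** 2).sum(axis=(1, 2)) / (n - 1)
    msc = n * ((rater - grand) ** 2).sum(axis=(1, 2)) / (k - 1)
    mse = ((y - subj - rater + grand) ** 2).sum(axis=(1, 2)) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (msr - mse) / denom
    out[denom == 0] = np.nan  # no variance anywhere: agreement undefined
    return out


def compute_feature_iccs(rater1: pd.DataFrame, rater2: pd.DataFrame) -> pd.Series:
    """Per-feature ICC(2,1) between two ratings tables (subjects x features)."""
    if list(rater1.columns) != list(rater2.columns):
        raise ValueError("rating tables must share the same feature columns")
    if len(rater1) != len(rater2):
        raise ValueError("rating tables must cover the same subjects")
    stack = np.stack(
        [rater1.to_numpy(dtype=float).T, rater2.to_numpy(dtype=float).T], axis=2
    )
    return pd.Series(icc_stack(stack), index=rater1.columns, name="icc")


@dataclass
class ICCFilterReport:
    retained: list[str]
    intra_icc: pd.Series
    inter_icc: pd.Series
    threshold: float
    n_input: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_input = len(self.intra_icc)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def filter_features(
    intra_icc: pd.Series, inter_icc: pd.Series, threshold: float = 0.8
) -> ICCFilterReport:
    """Retain features whose intra- AND inter-observer ICC is >= threshold.

    Undefined (NaN) ICCs never pass. The comparison is inclusive (>= 0.8).
    """
    if set(intra_icc.index) != set(inter_icc.index):
        raise ValueError("intra and inter tables cover different feature sets")
    inter_icc = inter_icc.reindex(intra_icc.index)
    ok = (intra_icc >= threshold) & (inter_icc >= threshold)
    retained = list(intra_icc.index[ok.fillna(False)])
    return ICCFilterReport(
        retained=retained,
        intra_icc=intra_icc,
        inter_icc=inter_icc,
        threshold=threshold,
    )
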