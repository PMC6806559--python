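"""Training-cohort z-score standardization of feature tables.

Parameters (per-feature mean and SD, population/1-n denominator) are
estimated on the training cohort only and reused verbatim on validation
data. Zero-SD features carry no information and are dropped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StandardizationParams:
    means: pd.Series
    sds: pd.Series  # population (ddof=0) SDs of retained features
    dropped: list[str] = field(default_factory=list)
    ddof: int = 0

    @property
    def features(self) -> list[str]:
        return list(self.means.index)

    def to_dict(self) -> dict:
        return {
            "ddof": self.ddof,
            "means": {k: float(v) for k, v in self.means.items()},
            "sds": {k: float(v) for k, v in self.sds.items()},
            "dropped": list(self.dropped),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(
            means=pd.Series(d["means"], dtype=float),
            sds=pd.Series(d["sds"], dtype=float),
            dropped=list(d.get("dropped", [])),
            ddof=int(d.get("ddof", 0)),
        )


def fit_standardizer(table: pd.DataFrame) -> StandardizationParams:
    """Estimate per-feature mean/SD on the training table."""
    if len(table) < 2:
        raise ValueError("need at least 2 training rows")
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=0)
    dropped = list(sds.index[(sds == 0) | ~np.isfinite(sds)])
    if dropped:
        warnings.warn(
            f"{len(dropped)} zero-variance feature(s) dropped from "
            f"standardization", stacklevel=2
        )
    keep = [c for c in table.columns if c not in dropped]
    return StandardizationParams(means=means[keep], sds=sds[keep], dropped=dropped)


def apply_standardizer(
    params: StandardizationParams, table: pd.DataFrame
) -> pd.DataFrame:
    """Z-score a table with (training) parameters; extra columns ignored."""
    missing = [f for f in params.features if f not in table.columns]
    if missing:
        raise ValueError(f"table is missing standardized feature(s): {missing[:5]}")
    sub = table[params.features]
    return (sub - params.means) / params.sds
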