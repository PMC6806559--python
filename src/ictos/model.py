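"""Interaction screening and the modified-covariate benefit model (ICTOS).

The pipeline mirrors a predictive-biomarker analysis: every standardized
radiomic feature is screened with a weighted Cox model containing treatment,
feature and their product (Wald p of the product ranks the features); a
greedy correlation filter removes redundant features; the survivors enter a
modified-covariate Cox fit — a Cox model on W = X (2T - 1) / 2 with no main
effects, whose coefficients gamma estimate the treatment-feature interaction
directly — followed by backward stepwise selection at the Wald level alpha.

The Induction Chemotherapy Outcome Score is the oriented linear predictor
ICTOS = -gamma . x: the fitted relative hazard of treatment for covariates x
is exp(gamma . x), so gamma . x < 0 means lower hazard under induction
chemotherapy, and the sign flip makes "score > 0" mean "predicted benefit".
Patients with score > 0 are labelled high, score <= 0 low.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from lifelines import CoxPHFitter

from .features.standardize import StandardizationParams, apply_standardizer

log = logging.getLogger(__name__)


class NoSignificantBenefitError(RuntimeError):
    """Backward selection removed every candidate: no benefit feature found."""


def _check_cohort(cohort: pd.DataFrame) -> None:
    if cohort["event"].sum() == 0:
        raise ValueError("no events in the cohort")
    if cohort["arm"].nunique() < 2:
        raise ValueError("both treatment arms must be present")


def _quiet_fit(cph: CoxPHFitter, df: pd.DataFrame, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cph.fit(df, duration_col="time_months", event_col="event", **kw)


@dataclass
class InteractionScreenResult:
    table: pd.DataFrame  # index: feature; columns: coef, p_interaction

    @property
    def ranking(self) -> list[str]:
        return list(self.table.index)


def screen_interactions(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    weights: np.ndarray | None = None,
) -> InteractionScreenResult:
    """Rank features by the Wald p of their treatment interaction.

    One weighted Cox fit per feature: hazard ~ exp(b1 T + b2 x + b3 T x);
    the table is sorted ascending in p(b3). Non-convergent fits get p = 1.
    """
    _check_cohort(cohort)
    base = pd.DataFrame(
        {
            "time_months": cohort["time_months"].to_numpy(dtype=float),
            "event": cohort["event"].to_numpy(dtype=int),
            "arm": cohort["arm"].to_numpy(dtype=float),
            "_w": np.ones(len(cohort)) if weights is None else np.asarray(weights, float),
        }
    )
    rows = []
    X = features.to_numpy(dtype=float)
    for j, name in enumerate(features.columns):
        df = base.copy()
        df["x"] = X[:, j]
        df["tx"] = df["arm"] * df["x"]
        try:
            cph = CoxPHFitter(penalizer=0.0)
            _quiet_fit(cph, df, weights_col="_w", robust=False)
            coef = float(cph.params_["tx"])
            p = float(cph.summary.loc["tx", "p"])
        except Exception as exc:
            log.warning("interaction fit failed for %s: %s", name, exc)
            coef, p = 0.0, 1.0
        rows.append((name, coef, p))
    table = pd.DataFrame(rows, columns=["feature", "coef", "p_interaction"])
    table = table.set_index("feature").sort_values("p_interaction", kind="stable")
    return InteractionScreenResult(table=table)


def redundancy_filter(
    ranking: list[str],
    features: pd.DataFrame | None = None,
    r_max: float = 0.8,
    max_features: int | None = 10,
    correlations: pd.DataFrame | None = None,
) -> list[str]:
    """Greedy redundancy filter in rank order.

    A feature is dropped when its absolute Pearson correlation with any
    already-retained (better-ranked) feature exceeds ``r_max``. Correlations
    are computed from ``features`` unless a precomputed ``correlations``
    matrix is given. Constant features have undefined correlation and are
    dropped with a warning.
    """
    if features is None and correlations is None:
        raise ValueError("need a feature table or a correlation matrix")

    def corr(a: str, b: str) -> float:
        if correlations is not None:
            return float(correlations.loc[a, b])
        return float(
            np.corrcoef(
                features[a].to_numpy(dtype=float),
                features[b].to_numpy(dtype=float),
            )[0, 1]
        )

    retained: list[str] = []
    for name in ranking:
        if features is not None and features[name].to_numpy(dtype=float).std() == 0:
            log.warning("feature %s is constant; dropped from candidates", name)
            continue
        if any(abs(corr(name, kept)) > r_max for kept in retained):
            continue
        retained.append(name)
        if max_features is not None and len(retained) >= max_features:
            break
    return retained


@dataclass
class ModifiedCovariateFit:
    gammas: pd.Series  # working-model coefficients on W = X (2T-1)/2
    p_values: pd.Series  # Wald p per coefficient
    log_likelihood: float


def fit_modified_covariate_cox(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    weights: np.ndarray | None = None,
) -> ModifiedCovariateFit:
    """Fit the modified-covariate working Cox model.

    Covariates are W = X (2T - 1) / 2 with T in {0, 1}; no main effects are
    included, so the partial likelihood targets the treatment-covariate
    interaction. IPTW weights enter as case weights; ties are handled by
    Efron's approximation.
    """
    _check_cohort(cohort)
    for a in (0, 1):
        if cohort.loc[cohort["arm"] == a, "event"].sum() < 1:
            raise ValueError(f"arm {a} has no events")
    X = features.to_numpy(dtype=float)
    if X.shape[1] == 0 or not np.any(X.std(axis=0) > 0):
        raise ValueError("no informative covariate to fit")
    sign = 2.0 * cohort["arm"].to_numpy(dtype=float) - 1.0
    W = X * (sign / 2.0)[:, None]
    df = pd.DataFrame(W, columns=features.columns)
    df["time_months"] = cohort["time_months"].to_numpy(dtype=float)
    df["event"] = cohort["event"].to_numpy(dtype=int)
    df["_w"] = np.ones(len(cohort)) if weights is None else np.asarray(weights, float)
    cph = CoxPHFitter(penalizer=0.0)
    _quiet_fit(cph, df, weights_col="_w", robust=False)
    return ModifiedCovariateFit(
        gammas=cph.params_.copy(),
        p_values=cph.summary["p"].copy(),
        log_likelihood=float(cph.log_likelihood_),
    )


def backward_select(
    candidates: list[str],
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    weights: np.ndarray | None = None,
    alpha: float = 0.05,
    standardization: StandardizationParams | None = None,
) -> "BenefitModel":
    """Backward stepwise selection on the modified-covariate model.

    Iteratively drops the coefficient with the largest Wald p until all
    remaining p < alpha. Ties drop the later-ranked candidate, making the
    procedure deterministic. Raises :class:`NoSignificantBenefitError` when
    nothing survives.
    """
    current = list(candidates)
    while current:
        fit = fit_modified_covariate_cox(features[current], cohort, weights)
        pvals = fit.p_values
        if (pvals < alpha).all():
            coefs = {name: -float(fit.gammas[name]) for name in current}
            return BenefitModel(
                features=current,
                coefficients=coefs,
                standardization=standardization,
                fit_p_values={k: float(v) for k, v in pvals.items()},
                log_likelihood=fit.log_likelihood,
            )
        worst_p = pvals.max()
        # tie-break: drop the later-ranked among the maximal p-values
        ties = [name for name in current if pvals[name] == worst_p]
        current.remove(ties[-1])
    raise NoSignificantBenefitError(
        f"no feature reached Wald p < {alpha}: no significant benefit features"
    )


@dataclass
class ICTOSScore:
    value: float
    label: str = field(init=False)  # "high" (> 0) or "low" (<= 0)

    def __post_init__(self) -> None:
        self.label = "high" if self.value > 0 else "low"


@dataclass
class BenefitModel:
    """Selected features, oriented coefficients and scoring rule.

    ``coefficients`` are on the ICTOS scale (positive score = predicted
    benefit from induction chemotherapy); they are the negated working-model
    gammas. Inputs to :meth:`score` must be standardized features, unless the
    model carries standardization parameters and ``standardized=False``.
    """

    features: list[str]
    coefficients: dict[str, float]
    standardization: StandardizationParams | None = None
    fit_p_values: dict[str, float] | None = None
    log_likelihood: float | None = None
    treatment_coding: str = "arm: 0 = CCRT alone, 1 = ICT+CCRT; W = x(2T-1)/2"
    cutoff: float = 0.0

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("a benefit model needs at least one feature")
        if set(self.features) != set(self.coefficients):
            raise ValueError("features and coefficients disagree")
        if not all(np.isfinite(list(self.coefficients.values()))):
            raise ValueError("coefficients must be finite")

    def score(self, values: Mapping[str, float]) -> ICTOSScore:
        """ICTOS of one patient from standardized feature values."""
        missing = [f for f in self.features if f not in values]
        if missing:
            raise ValueError(f"missing feature(s): {missing} (no imputation)")
        s = sum(self.coefficients[f] * float(values[f]) for f in self.features)
        return ICTOSScore(value=s)

    def score_table(
        self, table: pd.DataFrame, standardized: bool = True
    ) -> pd.DataFrame:
        """Score a feature table; returns 'ictos' and 'ictos_group' columns."""
        if not standardized:
            if self.standardization is None:
                raise ValueError("model has no standardization parameters")
            table = apply_standardizer(self.standardization, table)
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise ValueError(f"missing feature(s): {missing} (no imputation)")
        x = table[self.features].to_numpy(dtype=float)
        beta = np.array([self.coefficients[f] for f in self.features])
        scores = x @ beta
        return pd.DataFrame(
            {
                "ictos": scores,
                "ictos_group": np.where(scores > self.cutoff, "high", "low"),
            },
            index=table.index,
        )

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "features": list(self.features),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "cutoff": float(self.cutoff),
            "treatment_coding": self.treatment_coding,
        }
        if self.fit_p_values is not None:
            d["fit_p_values"] = self.fit_p_values
        if self.log_likelihood is not None:
            d["log_likelihood"] = self.log_likelihood
        if self.standardization is not None:
            d["standardization"] = self.standardization.to_dict()
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "BenefitModel":
        std = d.get("standardization")
        return cls(
            features=list(d["features"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            standardization=StandardizationParams.from_dict(std) if std else None,
            fit_p_values=d.get("fit_p_values"),
            log_likelihood=d.get("log_likelihood"),
            treatment_coding=d.get("treatment_coding", cls.treatment_coding),
            cutoff=float(d.get("cutoff", 0.0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenefitModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_published_model() -> BenefitModel:
    """The published three-feature ICTOS model (rounded coefficients).

    Ships as a read-only fixture: ICTOS = -0.668 skewness
    - 0.442 GLCM_variance + 0.410 GLRLM_LRHGLE on standardized
    contrast-enhanced T1 features. Usable for scoring without refitting.
    """
    ref = resources.files("ictos").joinpath("data/ictos_paper.yaml")
    return BenefitModel.from_dict(yaml.safe_load(ref.read_text()))
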