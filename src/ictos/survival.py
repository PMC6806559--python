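"""Weighted survival evaluation: Kaplan-Meier, arm contrasts, interaction
tests, log-rank power, and clinical risk stratification.

Kaplan-Meier estimation and Cox fits are weighted (IPTW case weights);
confidence bands use the Greenwood variance with the log(-log) transform.
The weighted log-rank test is the score test of the weighted Cox fit,
computed in closed form from weighted risk sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------
@dataclass
class KMCurve:
    """Weighted product-limit curve with Greenwood (log-log) 95% CIs."""

    survival: pd.Series  # index: time, values: S(t)
    ci_lower: pd.Series
    ci_upper: pd.Series
    n: float  # weighted size
    n_events: float  # weighted event count
    no_events: bool = False  # flat curve at 1; CIs undefined

    def survival_at(self, t: float) -> float:
        s = self.survival[self.survival.index <= t]
        return float(s.iloc[-1]) if len(s) else 1.0

    def ci_at(self, t: float) -> tuple[float, float]:
        lo = self.ci_lower[self.ci_lower.index <= t]
        hi = self.ci_upper[self.ci_upper.index <= t]
        return (
            float(lo.iloc[-1]) if len(lo) else np.nan,
            float(hi.iloc[-1]) if len(hi) else np.nan,
        )


def km_weighted(
    times: np.ndarray,
    events: np.ndarray,
    weights: np.ndarray | None = None,
    label: str | None = None,
) -> KMCurve:
    """Weighted Kaplan-Meier estimate with Greenwood log-log 95% CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if weights is None:
        weights = np.ones_like(times)
    weights = np.asarray(weights, dtype=float)
    if not (len(times) == len(events) == len(weights)):
        raise ValueError("times, events and weights must align")
    if np.any(weights < 0) or np.any(times < 0):
        raise ValueError("times and weights must be nonnegative")
    kmf = KaplanMeierFitter(label=label or "KM")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(times, events, weights=weights)
    surv = kmf.survival_function_.iloc[:, 0]
    ci = kmf.confidence_interval_survival_function_
    no_events = events.sum() == 0
    if no_events:
        log.info("no events: survival flat at 1, confidence band undefined")
    return KMCurve(
        survival=surv,
        ci_lower=ci.iloc[:, 0],
        ci_upper=ci.iloc[:, 1],
        n=float(weights.sum()),
        n_events=float(weights[events == 1].sum()),
        no_events=bool(no_events),
    )


# --------------------------------------------------------------------------
# Two-group comparison
# --------------------------------------------------------------------------
def weighted_logrank(
    times: np.ndarray,
    events: np.ndarray,
    group: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Weighted log-rank as the Cox score test: returns (chi2, p).

    At each event time the observed-minus-expected weighted events in group 1
    accumulate into U; the information uses the weighted risk-set fractions.
    With unit weights and no ties this is the classic log-rank statistic.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    w = np.ones_like(times) if weights is None else np.asarray(weights, float)
    u = 0.0
    info = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        yw = w[at_risk].sum()
        y1w = w[at_risk & (group == 1)].sum()
        died = (times == t) & (events == 1)
        dw = w[died].sum()
        d1w = w[died & (group == 1)].sum()
        frac = y1w / yw
        u += d1w - dw * frac
        info += dw * frac * (1.0 - frac)
    if info == 0:
        return 0.0, 1.0
    chi2 = u * u / info
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class ArmComparison:
    hr: float
    hr_ci: tuple[float, float]
    p_cox: float
    p_logrank: float
    n: dict = field(default_factory=dict)  # weighted size per arm


def compare_arms(
    cohort: pd.DataFrame, weights: np.ndarray | None = None
) -> ArmComparison:
    """Weighted univariate Cox HR (arm 1 vs arm 0) and weighted log-rank p."""
    arms = cohort["arm"].unique()
    if len(arms) < 2:
        raise ValueError("both arms must be present to compare")
    if cohort["event"].sum() < 1:
        raise ValueError("no events: nothing to compare")
    w = np.ones(len(cohort)) if weights is None else np.asarray(weights, float)
    df = pd.DataFrame(
        {
            "time_months": cohort["time_months"].to_numpy(float),
            "event": cohort["event"].to_numpy(int),
            "arm": cohort["arm"].to_numpy(float),
            "_w": w,
        }
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time_months", event_col="event", weights_col="_w")
    s = cph.summary.loc["arm"]
    _, p_lr = weighted_logrank(
        df["time_months"].to_numpy(), df["event"].to_numpy(),
        df["arm"].to_numpy(int), w,
    )
    return ArmComparison(
        hr=float(np.exp(s["coef"])),
        hr_ci=(float(np.exp(s["coef lower 95%"])), float(np.exp(s["coef upper 95%"]))),
        p_cox=float(s["p"]),
        p_logrank=p_lr,
        n={int(a): float(w[cohort["arm"].to_numpy() == a].sum()) for a in sorted(arms)},
    )


def interaction_test(
    cohort: pd.DataFrame,
    label: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Wald p of the arm x group product term in a weighted Cox model."""
    lab = np.asarray(label)
    if lab.dtype.kind in "OUS":
        lab = (lab == "high").astype(float)
    lab = lab.astype(float)
    arm = cohort["arm"].to_numpy(float)
    for a in (0.0, 1.0):
        for g in (0.0, 1.0):
            if not np.any((arm == a) & (lab == g)):
                raise ValueError(
                    f"empty stratum: arm={int(a)}, group={'high' if g else 'low'}"
                )
    df = pd.DataFrame(
        {
            "time_months": cohort["time_months"].to_numpy(float),
            "event": cohort["event"].to_numpy(int),
            "arm": arm,
            "grp": lab,
            "arm_grp": arm * lab,
            "_w": np.ones(len(cohort)) if weights is None else np.asarray(weights, float),
        }
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time_months", event_col="event", weights_col="_w")
    return float(cph.summary.loc["arm_grp", "p"])


# --------------------------------------------------------------------------
# Power / sample size
# --------------------------------------------------------------------------
@dataclass
class PowerSpec:
    n_patients: int
    n_events: int
    allocation: float = 0.5  # fraction in one arm
    hazard_ratio: float = 0.25
    alpha: float = 0.05  # two-sided

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("need at least one event")
        if not 0.0 < self.allocation < 1.0:
            raise ValueError("allocation must be in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def logrank_power(spec: PowerSpec) -> float:
    """Log-rank power by the event-driven normal approximation.

    power = Phi( sqrt(D p (1-p)) |ln HR| - z_{1-alpha/2} ), driven entirely
    by the event count D, the allocation fraction p and the alternative HR.
    At HR = 1 this degenerates to the lower tail Phi(-z), i.e. alpha/2.
    """
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    if spec.hazard_ratio == 1.0:
        log.info("HR = 1: power equals the one-sided significance level")
    effect = np.sqrt(spec.n_events * spec.allocation * (1.0 - spec.allocation))
    return float(stats.norm.cdf(effect * abs(np.log(spec.hazard_ratio)) - z))


def required_cohort_size(subgroup_n: int, prevalence: float) -> int:
    """Total cohort size so that the target subgroup reaches ``subgroup_n``.

    ``prevalence`` is the subgroup fraction; the quotient is rounded to the
    nearest integer (never below the subgroup size itself).
    """
    if not 0.0 < prevalence <= 1.0:
        raise ValueError("prevalence must be in (0, 1]")
    total = int(np.floor(subgroup_n / prevalence + 0.5))
    return max(total, subgroup_n)


# --------------------------------------------------------------------------
# Risk stratification of low-score patients
# --------------------------------------------------------------------------
@dataclass
class RiskStratification:
    table: pd.DataFrame  # id, risk_factor_count, risk_group
    count_threshold: int
    n_excluded: int
    arm_comparison: dict = field(default_factory=dict)  # risk_group -> ArmComparison
    risk_group_comparison: ArmComparison | None = None


def count_risk_factors(cohort: pd.DataFrame) -> pd.Series:
    """How many of the four high-risk factors each patient carries:
    N2-3, T4, primary tumor volume >= 34 ml, pEBV DNA >= 2000 copies/ml."""
    return (
        (cohort["n_stage"] >= 2).astype(int)
        + (cohort["t_stage"] == 4).astype(int)
        + (cohort["tumor_volume_ml"] >= 34.0).astype(int)
        + (cohort["pebv_dna"] >= 2000.0).astype(int)
    )


def stratify_low_ictos(
    cohort: pd.DataFrame, count_threshold: int = 3
) -> RiskStratification:
    """Split (low-score) patients into clinical high/low risk groups.

    A patient is high-risk with >= ``count_threshold`` of the four factors
    (default 3, the literal reading of "more than two"). Patients missing a
    required covariate are excluded and logged. Per-risk-group treatment-arm
    contrasts and the high-vs-low-risk contrast are attached where both
    groups have events.
    """
    needed = ["n_stage", "t_stage", "tumor_volume_ml", "pebv_dna"]
    ok = cohort[needed].notna().all(axis=1)
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.warning("%d patient(s) excluded for missing risk covariates", n_excluded)
    sub = cohort[ok].copy()
    counts = count_risk_factors(sub)
    group = np.where(counts >= count_threshold, "high-risk", "low-risk")
    table = pd.DataFrame(
        {"id": sub["id"].to_numpy(), "risk_factor_count": counts.to_numpy(),
         "risk_group": group},
    )
    sub = sub.assign(risk_group=group)

    per_group: dict[str, ArmComparison] = {}
    for g in ("low-risk", "high-risk"):
        gsub = sub[sub["risk_group"] == g]
        try:
            per_group[g] = compare_arms(gsub)
        except ValueError as exc:
            log.info("arm contrast skipped in %s group: %s", g, exc)
    risk_cmp = None
    if sub["risk_group"].nunique() == 2 and sub["event"].sum() > 0:
        tmp = sub.assign(arm=(sub["risk_group"] == "high-risk").astype(int))
        risk_cmp = compare_arms(tmp)
    return RiskStratification(
        table=table,
        count_threshold=count_threshold,
        n_excluded=n_excluded,
        arm_comparison=per_group,
        risk_group_comparison=risk_cmp,
    )


# --------------------------------------------------------------------------
# Summaries and plotting
# --------------------------------------------------------------------------
def survival_summary(
    cohort: pd.DataFrame,
    weights: np.ndarray | None = None,
    horizons: tuple[float, ...] = (36.0, 60.0),
) -> dict:
    """Per-arm KM read-offs at the horizons plus the arm contrast."""
    w = np.ones(len(cohort)) if weights is None else np.asarray(weights, float)
    out: dict = {"arms": {}}
    for a in sorted(cohort["arm"].unique()):
        sel = (cohort["arm"] == a).to_numpy()
        curve = km_weighted(
            cohort.loc[sel, "time_months"], cohort.loc[sel, "event"], w[sel]
        )
        entry = {"weighted_n": curve.n, "weighted_events": curve.n_events}
        for h in horizons:
            lo, hi = curve.ci_at(h)
            entry[f"ffs_{int(h)}m"] = curve.survival_at(h)
            entry[f"ffs_{int(h)}m_ci"] = (lo, hi)
        out["arms"][int(a)] = entry
    if cohort["arm"].nunique() == 2 and cohort["event"].sum() > 0:
        cmp = compare_arms(cohort, w)
        out["hr"] = cmp.hr
        out["hr_ci"] = cmp.hr_ci
        out["p_cox"] = cmp.p_cox
        out["p_logrank"] = cmp.p_logrank
    return out


def plot_km(curves: dict[str, KMCurve], path, title: str | None = None) -> None:
    """Write a step plot of one or more KM curves with their bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, c in curves.items():
        ax.step(c.survival.index, c.survival.values, where="post", label=name)
        if not c.no_events:
            ax.fill_between(
                c.ci_lower.index, c.ci_lower.values, c.ci_upper.values,
                step="post", alpha=0.15,
            )
    ax.set_xlabel("months")
    ax.set_ylabel("failure-free survival")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
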