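"""End-to-end orchestration of the two published experiments.

``run_training`` executes the observational-cohort arm of the study:
extract -> standardize -> ICC reliability filter -> IPTW -> interaction
screen -> redundancy filter -> modified-covariate fit -> backward selection,
yielding a BenefitModel. ``run_validation`` scores an independent
(randomized) cohort with a fitted or published model, splits at the 0
cutoff, and reports per-group arm contrasts, the treatment-interaction test,
and the clinical risk stratification of low-score patients.

Every run is reproducible from (config, seed); a provenance record (config
hash, seed, package version) is attached to the results and written next to
the output tables when an output directory is given.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import (
    apply_standardizer,
    extract_cohort_features,
    extract_patient_features,
    fit_standardizer,
)
from .icc import ICCFilterReport, compute_feature_iccs, filter_features
from .iptw import BalanceReport, balance_report, compute_weights, fit_propensity
from .model import (
    BenefitModel,
    InteractionScreenResult,
    backward_select,
    redundancy_filter,
    screen_interactions,
)
from .phantom import perturb_mask
from .preprocess import PreprocessConfig
from .survival import (
    RiskStratification,
    interaction_test,
    stratify_low_ictos,
    survival_summary,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    icc_threshold: float = 0.8
    icc_subjects: int = 15  # patients re-segmented for reliability
    icc_intra_jitter: int = 1  # same observer, second pass
    icc_inter_jitter: int = 1  # second observer
    r_max: float = 0.8
    alpha: float = 0.05
    max_candidates: int = 10
    iptw: bool = True
    iptw_stabilized: bool = True
    iptw_truncation: tuple[float, float] | None = (0.01, 0.99)
    screen_weighted: bool = True
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.icc_threshold <= 1.0:
            raise ValueError("icc_threshold must be in (0, 1]")
        if not 0.0 < self.r_max <= 1.0:
            raise ValueError("r_max must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _provenance(config: RunConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "package_version": __version__,
    }


def reliability_tables(
    scans: dict, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Re-segment the first ``icc_subjects`` patients and re-extract.

    Returns (original, intra-repeat, inter-repeat) feature tables for the
    reliability subset, emulating a second pass by the same observer (small
    boundary jitter) and a second observer (larger jitter).
    """
    subjects = list(scans)[: config.icc_subjects]
    rng = np.random.default_rng(config.seed + 101)
    rows_orig, rows_intra, rows_inter = {}, {}, {}
    for pid in subjects:
        scan = scans[pid]
        seeds = rng.integers(0, 2**31 - 1, size=2)
        m_intra = perturb_mask(scan.mask, config.icc_intra_jitter, int(seeds[0]))
        m_inter = perturb_mask(scan.mask, config.icc_inter_jitter, int(seeds[1]))
        rows_orig[pid] = extract_patient_features(
            scan.volumes, scan.mask, config=config.preprocess
        )
        rows_intra[pid] = extract_patient_features(
            scan.volumes, m_intra, config=config.preprocess
        )
        rows_inter[pid] = extract_patient_features(
            scan.volumes, m_inter, config=config.preprocess
        )
    return (
        pd.DataFrame.from_dict(rows_orig, orient="index"),
        pd.DataFrame.from_dict(rows_intra, orient="index"),
        pd.DataFrame.from_dict(rows_inter, orient="index"),
    )


@dataclass
class TrainingResult:
    model: BenefitModel
    features: pd.DataFrame  # standardized training features
    weights: np.ndarray
    icc_report: ICCFilterReport
    balance: BalanceReport | None
    screen: InteractionScreenResult
    candidates: list[str]
    provenance: dict


def run_training(
    scans: dict,
    clinical: pd.DataFrame,
    config: RunConfig | None = None,
) -> TrainingResult:
    """Fit the benefit model on an (observational) training cohort."""
    config = config or RunConfig()
    clinical = clinical.reset_index(drop=True)
    if set(clinical["id"]) - set(scans):
        raise RuntimeError("stage extract: scans missing for some patients")
    if clinical["event"].sum() == 0:
        raise RuntimeError("stage modeling: no events in the training cohort")

    log.info("stage extract: %d patients", len(clinical))
    feats = extract_cohort_features(
        {pid: scans[pid] for pid in clinical["id"]}, config=config.preprocess
    ).loc[clinical["id"]]

    log.info("stage standardize")
    params = fit_standardizer(feats)
    std = apply_standardizer(params, feats)

    log.info("stage icc: %d reliability subjects", config.icc_subjects)
    orig, intra, inter = reliability_tables(scans, config)
    icc_intra = compute_feature_iccs(orig, intra)
    icc_inter = compute_feature_iccs(orig, inter)
    icc_rep = filter_features(icc_intra, icc_inter, config.icc_threshold)
    retained = [f for f in icc_rep.retained if f in std.columns]
    log.info("stage icc: %d / %d features retained", len(retained), len(feats.columns))
    if not retained:
        raise RuntimeError("stage icc: no feature passed the reliability filter")

    balance = None
    if config.iptw:
        log.info("stage iptw")
        scores = fit_propensity(clinical)
        weights = compute_weights(
            scores,
            clinical["arm"].to_numpy(),
            stabilized=config.iptw_stabilized,
            truncation=config.iptw_truncation,
        )
        balance = balance_report(clinical, weights)
    else:
        weights = np.ones(len(clinical))

    log.info("stage screen: %d features", len(retained))
    screen = screen_interactions(
        std[retained], clinical, weights if config.screen_weighted else None
    )
    candidates = redundancy_filter(
        screen.ranking, std, r_max=config.r_max, max_features=config.max_candidates
    )
    log.info("stage select: %d candidates -> backward selection", len(candidates))
    model = backward_select(
        candidates, std, clinical, weights, alpha=config.alpha,
        standardization=_restrict(params, candidates),
    )
    # keep only the selected features' standardization in the shipped model
    model.standardization = _restrict(params, model.features)

    result = TrainingResult(
        model=model,
        features=std,
        weights=weights,
        icc_report=icc_rep,
        balance=balance,
        screen=screen,
        candidates=candidates,
        provenance=_provenance(config, "training"),
    )
    if config.output_dir:
        _write_training(result, config)
    return result


def _restrict(params, names):
    from .features.standardize import StandardizationParams

    keep = [n for n in names if n in params.means.index]
    return StandardizationParams(
        means=params.means[keep], sds=params.sds[keep], dropped=[], ddof=params.ddof
    )


def _write_training(result: TrainingResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.model.to_yaml(out / "model.yaml")
    result.features.to_csv(out / "features_standardized.csv")
    result.screen.table.to_csv(out / "interaction_screen.csv")
    if result.balance is not None:
        result.balance.table.to_csv(out / "balance_report.csv")
    pd.Series(result.weights, name="weight").to_csv(out / "iptw_weights.csv")
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)


@dataclass
class ValidationResult:
    scores: pd.DataFrame  # id-indexed: ictos, ictos_group
    overall: dict
    by_group: dict  # "high"/"low" -> survival summary
    p_interaction: float | None
    stratification: RiskStratification | None
    provenance: dict


def run_validation(
    scans: dict,
    clinical: pd.DataFrame,
    model: BenefitModel,
    config: RunConfig | None = None,
) -> ValidationResult:
    """Score and evaluate an independent (randomized) validation cohort."""
    config = config or RunConfig()
    clinical = clinical.reset_index(drop=True)
    feats = extract_cohort_features(
        {pid: scans[pid] for pid in clinical["id"]}, config=config.preprocess
    ).loc[clinical["id"]]
    missing = [f for f in model.features if f not in feats.columns]
    if missing:
        raise RuntimeError(f"stage score: model features absent: {missing}")
    scores = model.score_table(feats, standardized=model.standardization is None)

    labels = scores["ictos_group"].to_numpy()
    overall = survival_summary(clinical)
    by_group: dict[str, dict] = {}
    for g in ("high", "low"):
        sel = labels == g
        if sel.any():
            by_group[g] = survival_summary(clinical[sel])
            by_group[g]["n"] = int(sel.sum())
    p_int: float | None
    try:
        p_int = interaction_test(clinical, labels)
    except ValueError as exc:
        log.info("interaction test skipped: %s", exc)
        p_int = None

    strat = None
    low_sel = labels == "low"
    if low_sel.any():
        strat = stratify_low_ictos(clinical[low_sel])

    result = ValidationResult(
        scores=scores.set_index(clinical["id"]),
        overall=overall,
        by_group=by_group,
        p_interaction=p_int,
        stratification=strat,
        provenance=_provenance(config, "validation"),
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.scores.to_csv(out / "scores.csv")
        summary = {
            "overall": overall,
            "by_group": by_group,
            "p_interaction": p_int,
            "provenance": result.provenance,
        }
        with open(out / "validation_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return result
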