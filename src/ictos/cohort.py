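"""Synthetic two-arm survival cohorts with a planted treatment-benefit subgroup.

Each patient carries three latent texture axes z = (z_skew, z_hetero, z_run),
standard normal and independent. They drive both the phantom's texture knobs
(so the axes are recoverable from images) and the patient-specific treatment
effect: the log hazard ratio of induction chemotherapy (arm 1) versus
chemoradiotherapy alone (arm 0) is

    delta(z) = base_treatment_loghr + true_benefit_coefs . z

so a benefit subgroup genuinely exists whenever the coefficients are nonzero.
Event times are exponential, calibrated so a baseline-risk control patient
has the requested 5-year failure-free fraction; clinical covariates carry
modest prognostic effects and, when ``confounding_strength`` > 0, also drive
arm assignment through a logistic model (the observational scenario).
Censoring is a random early-censoring fraction plus administrative censoring.
Time unit: months. Event: first failure or death (composite FFS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .images import PatientScan
from .phantom import TexturePhantomSpec, generate_phantom

#: months in five years — the calibration horizon for baseline_5yr_ffs
FIVE_YEARS = 60.0

# prognostic log-hazard effects of the high-risk clinical factors
_PROGNOSTIC = {
    "volume_high": 0.30,
    "pebv_high": 0.30,
    "t4": 0.25,
    "n23": 0.25,
}

CLINICAL_COLUMNS = [
    "id", "arm", "time_months", "event", "age", "sex", "t_stage", "n_stage",
    "stage", "nodal_necrosis", "tumor_volume_ml", "pebv_dna",
]


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 250
    arm_ratio: float = 0.5  # fraction assigned to ICT+CCRT in expectation
    baseline_5yr_ffs: float = 0.65
    base_treatment_loghr: float = -0.66
    true_benefit_coefs: tuple[float, float, float] = (0.668, 0.442, -0.410)
    confounding_strength: float = 0.0
    censor_rate: float = 0.15
    admin_censor_time: float = 84.0  # months
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.baseline_5yr_ffs < 1.0:
            raise ValueError("baseline_5yr_ffs must be in (0, 1)")
        if not 0.0 <= self.arm_ratio <= 1.0:
            raise ValueError("arm_ratio must be in [0, 1]")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be positive")

    @property
    def baseline_hazard(self) -> float:
        """Monthly exponential hazard giving S(60) = baseline_5yr_ffs."""
        return -np.log(self.baseline_5yr_ffs) / FIVE_YEARS


@dataclass
class SyntheticCohort:
    table: pd.DataFrame  # clinical/survival table, one row per patient
    truth: pd.DataFrame  # latent axes and true per-patient benefit log-HR
    scans: dict[str, PatientScan] = field(default_factory=dict)

    def write_csv(self, path: str | Path) -> None:
        self.table[CLINICAL_COLUMNS].to_csv(path, index=False)


def phantom_spec_for_latents(
    z_skew: float,
    z_hetero: float,
    z_run: float,
    seed: int,
    grid_shape: tuple[int, int, int] = (3, 44, 44),
    roi_radius: int = 10,
) -> TexturePhantomSpec:
    """Map one patient's latent axes to phantom texture knobs (monotone)."""
    return TexturePhantomSpec(
        grid_shape=grid_shape,
        roi_radius=roi_radius,
        target_skew=1.2 * z_skew,
        heterogeneity=max(1.0 + 0.8 * z_hetero, 0.0),
        run_structure=max(1.5 + 0.8 * z_run, 0.0),
        noise_sd=2.0,
        seed=seed,
    )


def _clinical_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = np.clip(rng.normal(45.0, 10.0, n), 18, 75).round(0)
    sex = rng.binomial(1, 0.75, n)  # 1 = male
    t_stage = rng.choice([1, 2, 3, 4], size=n, p=[0.03, 0.08, 0.57, 0.32])
    n_stage = rng.choice([1, 2, 3], size=n, p=[0.48, 0.38, 0.14])
    stage = np.where((t_stage == 4) | (n_stage == 3), 4, 3)  # overall AJCC
    necrosis = rng.binomial(1, 0.30, n)
    volume = np.exp(rng.normal(np.log(30.0), 0.5, n)).round(1)
    pebv = np.exp(rng.normal(np.log(2500.0), 1.5, n)).round(0)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "stage": stage,
            "nodal_necrosis": necrosis,
            "tumor_volume_ml": volume,
            "pebv_dna": pebv,
        }
    )


def prognostic_score(table: pd.DataFrame) -> np.ndarray:
    """Fixed clinical log-hazard score (uncentered)."""
    return (
        _PROGNOSTIC["volume_high"] * (table["tumor_volume_ml"] >= 34.0)
        + _PROGNOSTIC["pebv_high"] * (table["pebv_dna"] >= 2000.0)
        + _PROGNOSTIC["t4"] * (table["t_stage"] == 4)
        + _PROGNOSTIC["n23"] * (table["n_stage"] >= 2)
    ).to_numpy(dtype=float)


def generate_cohort(
    spec: CohortSpec,
    with_images: bool = False,
    grid_shape: tuple[int, int, int] = (3, 44, 44),
    roi_radius: int = 10,
) -> SyntheticCohort:
    """Generate the cohort table (and, optionally, the linked phantom scans)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    clin = _clinical_covariates(rng, n)
    z = rng.standard_normal((n, 3))
    lp_prog = prognostic_score(clin)
    lp_prog = lp_prog - lp_prog.mean()  # keep marginal risk at baseline

    # arm assignment: randomized when confounding_strength == 0
    base_logit = np.log(spec.arm_ratio / (1.0 - spec.arm_ratio)) if 0 < spec.arm_ratio < 1 else None
    if spec.arm_ratio in (0.0, 1.0):
        arm = np.full(n, int(spec.arm_ratio))
    elif spec.confounding_strength == 0.0:
        arm = rng.binomial(1, spec.arm_ratio, n)
    else:
        sd = lp_prog.std()
        zscore = lp_prog / sd if sd > 0 else np.zeros(n)
        p_arm = 1.0 / (1.0 + np.exp(-(base_logit + spec.confounding_strength * zscore)))
        arm = rng.binomial(1, p_arm)

    benefit_loghr = spec.base_treatment_loghr + z @ np.asarray(spec.true_benefit_coefs)
    hazard = spec.baseline_hazard * np.exp(lp_prog + arm * benefit_loghr)
    event_time = rng.exponential(1.0 / hazard)

    # random early censoring: the selected fraction is censored strictly
    # before its event; everyone is administratively censored at the horizon
    time = event_time.copy()
    event = np.ones(n, dtype=int)
    censored = rng.random(n) < spec.censor_rate
    time[censored] = rng.random(censored.sum()) * event_time[censored]
    event[censored] = 0
    over = time > spec.admin_censor_time
    time[over] = spec.admin_censor_time
    event[over] = 0

    ids = [f"P{i:04d}" for i in range(n)]
    table = clin.copy()
    table.insert(0, "id", ids)
    table.insert(1, "arm", arm)
    table.insert(2, "time_months", np.round(time, 3))
    table.insert(3, "event", event)

    truth = pd.DataFrame(
        {
            "id": ids,
            "latent_skew": z[:, 0],
            "latent_hetero": z[:, 1],
            "latent_run": z[:, 2],
            "benefit_loghr": benefit_loghr,
        }
    )

    scans: dict[str, PatientScan] = {}
    if with_images:
        child_seeds = rng.integers(0, 2**31 - 1, size=n)
        # tumor size varies across patients (radius within the grid's limits)
        max_r = max(int(0.45 * min(grid_shape[1], grid_shape[2])) - 2, 5)
        radii = rng.integers(max(roi_radius - 2, 4), min(roi_radius + 3, max_r + 1), size=n)
        for i, pid in enumerate(ids):
            pspec = phantom_spec_for_latents(
                z[i, 0], z[i, 1], z[i, 2], seed=int(child_seeds[i]),
                grid_shape=grid_shape, roi_radius=int(radii[i]),
            )
            volumes, mask = generate_phantom(pspec)
            scans[pid] = PatientScan(patient_id=pid, volumes=volumes, mask=mask)

    return SyntheticCohort(table=table, truth=truth, scans=scans)
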