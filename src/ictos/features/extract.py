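"""ROI- and patient-level feature extraction.

The per-ROI pipeline is: optional in-plane resampling, whole-volume z-score
normalization, fixed-bin-count discretization, then first-order, shape, GLCM
(4 directions x 2 distances) and GLRLM (4 directions) features — 273 values.
Per patient the three sequences are extracted independently and concatenated
with sequence-label prefixes — 819 values.
"""

from __future__ import annotations

import pandas as pd

from ..images import MRVolume, PatientScan, ROIMask, SEQUENCE_LABELS
from ..preprocess import PreprocessConfig, discretize, normalize_intensity, resample_inplane
from .catalogue import FEATURES_PER_PATIENT, FEATURES_PER_ROI, FeatureCatalogue, default_catalogue
from .firstorder import intensity_features
from .glcm import glcm_features, glcm_matrix
from .glrlm import glrlm_features, glrlm_matrix
from .shape import shape_features


def extract_roi_features(
    vol: MRVolume,
    mask: ROIMask,
    catalogue: FeatureCatalogue | None = None,
    config: PreprocessConfig | None = None,
) -> dict[str, float]:
    """Extract the 273 per-ROI features from one sequence."""
    cat = catalogue or default_catalogue()
    cfg = config or PreprocessConfig()
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    vol, mask = resample_inplane(vol, mask, cfg.target_spacing_mm)
    if cfg.normalization == "zscore":
        vol = normalize_intensity(vol)
    gray = discretize(vol, mask, cfg.n_bins)

    out: dict[str, float] = {}
    for k, v in intensity_features(vol, mask, n_bins=cfg.n_bins).items():
        out[f"firstorder_{k}"] = v
    for k, v in shape_features(mask).items():
        out[f"shape_{k}"] = v
    for d in cat.distances:
        for a in cat.angles:
            feats = glcm_features(glcm_matrix(gray, distance=d, angle=a))
            for k, v in feats.items():
                out[f"glcm_{k}_d{d}_a{a}"] = v
    for a in cat.angles:
        feats = glrlm_features(glrlm_matrix(gray, angle=a))
        for k, v in feats.items():
            out[f"glrlm_{k}_a{a}"] = v

    assert len(out) == FEATURES_PER_ROI, (
        f"extracted {len(out)} features per ROI, expected {FEATURES_PER_ROI}"
    )
    return out


def extract_patient_features(
    scan_or_volumes,
    mask: ROIMask | None = None,
    catalogue: FeatureCatalogue | None = None,
    config: PreprocessConfig | None = None,
) -> dict[str, float]:
    """Extract the 819 per-patient features across T1, T2 and T1C.

    Accepts a :class:`PatientScan` or a ``{label: MRVolume}`` dict plus the
    shared mask. All three sequences must be present; nothing is imputed.
    """
    if isinstance(scan_or_volumes, PatientScan):
        volumes, mask = scan_or_volumes.volumes, scan_or_volumes.mask
    else:
        volumes = scan_or_volumes
    if mask is None:
        raise ValueError("a tumor mask is required")
    missing = [s for s in SEQUENCE_LABELS if s not in volumes]
    if missing:
        raise ValueError(f"missing sequence(s): {', '.join(missing)}")

    out: dict[str, float] = {}
    for label in SEQUENCE_LABELS:
        roi_feats = extract_roi_features(volumes[label], mask, catalogue, config)
        for k, v in roi_feats.items():
            out[f"{label}_{k}"] = v
    assert len(out) == FEATURES_PER_PATIENT
    return out


def extract_cohort_features(
    scans: dict[str, PatientScan],
    catalogue: FeatureCatalogue | None = None,
    config: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Feature table for a cohort: one row per patient, 819 columns."""
    rows = {}
    for pid, scan in scans.items():
        rows[pid] = extract_patient_features(scan, catalogue=catalogue, config=config)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df
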