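"""Mask-aware 2D gray-level co-occurrence matrices and their features.

Pairs are counted per axial slice at the given (distance, direction) offset,
only where both voxels lie inside the ROI; slice counts are summed, the
matrix symmetrized, then normalized once to sum 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..preprocess import GrayLevelMap

# (row, col) steps; directions follow the usual image convention where
# 0 deg is along the row (to the right) and 90 deg is up the column axis.
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_EPS = np.finfo(float).tiny


@dataclass
class GLCM:
    matrix: np.ndarray  # (n_bins, n_bins), sums to 1 unless degenerate
    n_pairs: int
    degenerate: bool  # no valid in-ROI pair at this offset


def glcm_matrix(gray: GrayLevelMap, distance: int = 1, angle: int = 0) -> GLCM:
    """Normalized symmetric co-occurrence matrix at one offset."""
    if angle not in ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(ANGLE_OFFSETS)}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if gray.roi_voxel_count == 0:
        raise ValueError("empty ROI")
    dr, dc = ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    ng = gray.n_bins
    labels = gray.labels
    counts = np.zeros(ng * ng, dtype=np.int64)
    n_slices, n_rows, n_cols = labels.shape
    for k in range(n_slices):
        sl = labels[k]
        r0, r1 = max(0, -dr), min(n_rows, n_rows - dr)
        c0, c1 = max(0, -dc), min(n_cols, n_cols - dc)
        a = sl[r0:r1, c0:c1]
        b = sl[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = (a > 0) & (b > 0)
        if valid.any():
            flat = (a[valid] - 1) * ng + (b[valid] - 1)
            counts += np.bincount(flat, minlength=ng * ng)
    mat = counts.reshape(ng, ng).astype(float)
    mat = mat + mat.T
    total = mat.sum()
    if total == 0:
        return GLCM(matrix=np.zeros((ng, ng)), n_pairs=0, degenerate=True)
    return GLCM(matrix=mat / total, n_pairs=int(counts.sum()), degenerate=False)


def glcm_features(glcm: GLCM | np.ndarray) -> dict[str, float]:
    """The 24 co-occurrence features of a normalized symmetric matrix.

    ``variance`` is the joint (gray-level) variance
    sum_ij P(i,j) (i - mu)^2 with mu = sum_ij P(i,j) i — the quantity the
    benefit model uses. Degenerate matrices (no pair, or a single occupied
    level) fall back to the documented conventions: dispersion-type features
    0, correlation 0, energy/maximum probability from the matrix as is.
    """
    if isinstance(glcm, GLCM):
        P = glcm.matrix
        degenerate = glcm.degenerate
    else:
        P = np.asarray(glcm, dtype=float)
        degenerate = P.sum() == 0
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    out: dict[str, float] = {}
    if degenerate:
        return {name: 0.0 for name in _FEATURE_NAMES}

    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # == py by symmetry
    mu = float((px * i).sum())
    var = float((P * (ii - mu) ** 2).sum())

    # p_{x+y}(k), k = 2..2Ng  and  p_{x-y}(k), k = 0..Ng-1
    psum = np.zeros(2 * ng + 1)
    np.add.at(psum, (ii + jj).ravel(), P.ravel())
    pdiff = np.zeros(ng)
    np.add.at(pdiff, np.abs(ii - jj).ravel(), P.ravel())
    ks = np.arange(2 * ng + 1)
    kd = np.arange(ng)

    out["autocorrelation"] = float((P * ii * jj).sum())
    out["joint_average"] = mu
    centered = ii + jj - 2.0 * mu
    out["cluster_prominence"] = float((P * centered**4).sum())
    out["cluster_shade"] = float((P * centered**3).sum())
    out["cluster_tendency"] = float((P * centered**2).sum())
    out["contrast"] = float((P * (ii - jj) ** 2).sum())
    out["correlation"] = (
        (out["autocorrelation"] - mu * mu) / var if var > 0 else 0.0
    )
    da = float((pdiff * kd).sum())
    out["difference_average"] = da
    out["difference_entropy"] = float(-(pdiff * np.log2(pdiff + _EPS))[pdiff > 0].sum())
    out["difference_variance"] = float((pdiff * (kd - da) ** 2).sum())
    out["joint_energy"] = float((P**2).sum())
    out["joint_entropy"] = float(-(P * np.log2(P + _EPS))[P > 0].sum())

    hx = float(-(px * np.log2(px + _EPS))[px > 0].sum())
    pxy = np.outer(px, px)
    hxy = out["joint_entropy"]
    nz = (P > 0) | (pxy > 0)
    hxy1 = float(-(P[nz] * np.log2(pxy[nz] + _EPS)).sum())
    hxy2 = float(-(pxy[nz] * np.log2(pxy[nz] + _EPS)).sum())
    out["imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    absdiff = np.abs(ii - jj)
    out["inverse_difference"] = float((P / (1.0 + absdiff)).sum())
    out["inverse_difference_normalized"] = float((P / (1.0 + absdiff / ng)).sum())
    out["inverse_difference_moment"] = float((P / (1.0 + absdiff**2)).sum())
    out["inverse_difference_moment_normalized"] = float(
        (P / (1.0 + absdiff**2 / ng**2)).sum()
    )
    offdiag = absdiff > 0
    out["inverse_variance"] = float((P[offdiag] / absdiff[offdiag] ** 2).sum())
    out["maximum_probability"] = float(P.max())
    sa = float((psum * ks).sum())
    out["sum_average"] = sa
    out["sum_entropy"] = float(-(psum * np.log2(psum + _EPS))[psum > 0].sum())
    out["sum_variance"] = float((psum * (ks - sa) ** 2).sum())
    out["variance"] = var
    return out


_FEATURE_NAMES = [
    "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "joint_energy",
    "joint_entropy", "imc1", "imc2", "inverse_difference",
    "inverse_difference_normalized", "inverse_difference_moment",
    "inverse_difference_moment_normalized", "inverse_variance",
    "maximum_probability", "sum_average", "sum_entropy", "sum_variance",
    "variance",
]
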