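"""Mask-aware 2D gray-level run-length matrices and their features.

A run is a maximal streak of in-ROI voxels sharing a gray level along one of
the four 2D directions; runs are counted per axial slice and summed over
slices into R(i, l).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..preprocess import GrayLevelMap


@dataclass
class GLRLM:
    matrix: np.ndarray  # (n_bins, max_run_length): R[i-1, l-1]
    n_runs: int


def _lines(slice_labels: np.ndarray, angle: int) -> list[np.ndarray]:
    """All lattice lines of one slice along the given direction."""
    if angle == 0:
        return list(slice_labels)  # rows
    if angle == 90:
        return list(slice_labels.T)  # columns
    if angle == 135:  # main diagonals (offset (-1,-1) direction)
        r, c = slice_labels.shape
        return [np.diagonal(slice_labels, k) for k in range(-r + 1, c)]
    if angle == 45:  # anti-diagonals (offset (-1,+1) direction)
        flipped = np.fliplr(slice_labels)
        r, c = flipped.shape
        return [np.diagonal(flipped, k) for k in range(-r + 1, c)]
    raise ValueError("angle must be one of 0, 45, 90, 135")


def glrlm_matrix(gray: GrayLevelMap, angle: int = 0) -> GLRLM:
    """Run-length matrix along one direction, summed over slices."""
    if gray.roi_voxel_count == 0:
        raise ValueError("empty ROI")
    ng = gray.n_bins
    max_len = max(gray.labels.shape[1], gray.labels.shape[2])
    R = np.zeros((ng, max_len), dtype=np.int64)
    for sl in gray.labels:
        segs = _lines(sl, angle)
        # concatenate lines with a 0 separator so runs cannot cross lines
        buf = np.full(sum(len(s) + 1 for s in segs), 0, dtype=np.int64)
        pos = 0
        for s in segs:
            buf[pos : pos + len(s)] = s
            pos += len(s) + 1
        change = np.flatnonzero(np.diff(buf)) + 1
        starts = np.concatenate(([0], change))
        lengths = np.diff(np.concatenate((starts, [len(buf)])))
        values = buf[starts]
        keep = values > 0
        np.add.at(R, (values[keep] - 1, lengths[keep] - 1), 1)
    return GLRLM(matrix=R, n_runs=int(R.sum()))


def glrlm_features(glrlm: GLRLM | np.ndarray) -> dict[str, float]:
    """The 13 run-length features, including LRHGLE."""
    R = glrlm.matrix if isinstance(glrlm, GLRLM) else np.asarray(glrlm, float)
    nr = float(R.sum())
    if nr == 0:
        raise ValueError("run-length matrix has no runs")
    R = R.astype(float)
    ng, lmax = R.shape
    i = np.arange(1, ng + 1)[:, None]
    l = np.arange(1, lmax + 1)[None, :]
    np_vox = float((R * l).sum())  # voxels covered

    ri = R.sum(axis=1)  # runs per gray level
    rl = R.sum(axis=0)  # runs per length
    iv = i.ravel()
    lv = l.ravel()

    out: dict[str, float] = {}
    out["sre"] = float((rl / lv**2).sum()) / nr
    out["lre"] = float((rl * lv**2).sum()) / nr
    out["gln"] = float((ri**2).sum()) / nr
    out["rln"] = float((rl**2).sum()) / nr
    out["rp"] = nr / np_vox
    out["lglre"] = float((ri / iv**2).sum()) / nr
    out["hglre"] = float((ri * iv**2).sum()) / nr
    out["srlgle"] = float((R / (i**2 * l**2)).sum()) / nr
    out["srhgle"] = float((R * i**2 / l**2).sum()) / nr
    out["lrlgle"] = float((R * l**2 / i**2).sum()) / nr
    out["lrhgle"] = float((R * i**2 * l**2).sum()) / nr
    p = R / nr
    mu_i = float((p * i).sum())
    out["glv"] = float((p * (i - mu_i) ** 2).sum())
    mu_l = float((p * l).sum())
    out["rlv"] = float((p * (l - mu_l) ** 2).sum())
    return out
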