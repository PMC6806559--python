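"""Independent brute-force oracles used only by the tests.

Everything here is written as plain loops straight from the definitions and
deliberately shares no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(labels: np.ndarray, n_levels: int, distance: int, angle: int) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix by exhaustive pair listing."""
    dr, dc = ANGLE_STEPS[angle]
    dr, dc = dr * distance, dc * distance
    rows, cols = labels.shape
    mat = np.zeros((n_levels, n_levels))
    for r in range(rows):
        for c in range(cols):
            i = labels[r, c]
            if i <= 0:
                continue
            for sr, sc in ((dr, dc), (-dr, -dc)):  # both directions
                r2, c2 = r + sr, c + sc
                if 0 <= r2 < rows and 0 <= c2 < cols and labels[r2, c2] > 0:
                    mat[i - 1, labels[r2, c2] - 1] += 1
    total = mat.sum()
    return mat / total if total > 0 else mat


def brute_glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 24 co-occurrence features by naive double summation."""
    ng = P.shape[0]
    tiny = np.finfo(float).tiny
    mu = sum(P[i, j] * (i + 1) for i in range(ng) for j in range(ng))
    var = sum(P[i, j] * (i + 1 - mu) ** 2 for i in range(ng) for j in range(ng))
    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]

    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + P[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + P[i, j]

    out = {}
    out["autocorrelation"] = sum(
        P[i, j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng)
    )
    out["joint_average"] = mu
    for name, power in (("cluster_prominence", 4), ("cluster_shade", 3),
                        ("cluster_tendency", 2)):
        out[name] = sum(
            P[i, j] * (i + 1 + j + 1 - 2 * mu) ** power
            for i in range(ng) for j in range(ng)
        )
    out["contrast"] = sum(
        P[i, j] * (i - j) ** 2 for i in range(ng) for j in range(ng)
    )
    out["correlation"] = (out["autocorrelation"] - mu * mu) / var if var > 0 else 0.0
    da = sum(k * v for k, v in pdiff.items())
    out["difference_average"] = da
    out["difference_entropy"] = -sum(
        v * math.log2(v + tiny) for v in pdiff.values() if v > 0
    )
    out["difference_variance"] = sum(v * (k - da) ** 2 for k, v in pdiff.items())
    out["joint_energy"] = sum(
        P[i, j] ** 2 for i in range(ng) for j in range(ng)
    )
    out["joint_entropy"] = -sum(
        P[i, j] * math.log2(P[i, j] + tiny)
        for i in range(ng) for j in range(ng) if P[i, j] > 0
    )
    hx = -sum(p * math.log2(p + tiny) for p in px if p > 0)
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * px[j] + tiny)
        for i in range(ng) for j in range(ng)
        if P[i, j] > 0 or px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log2(px[i] * px[j] + tiny)
        for i in range(ng) for j in range(ng)
        if P[i, j] > 0 or px[i] * px[j] > 0
    )
    out["imc1"] = (out["joint_entropy"] - hxy1) / hx if hx > 0 else 0.0
    out["imc2"] = math.sqrt(
        max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - out["joint_entropy"])))
    )
    out["inverse_difference"] = sum(
        P[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    out["inverse_difference_normalized"] = sum(
        P[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    out["inverse_difference_moment"] = sum(
        P[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    out["inverse_difference_moment_normalized"] = sum(
        P[i, j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
    )
    out["inverse_variance"] = sum(
        P[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    out["maximum_probability"] = float(P.max())
    sa = sum(k * v for k, v in psum.items())
    out["sum_average"] = sa
    out["sum_entropy"] = -sum(
        v * math.log2(v + tiny) for v in psum.values() if v > 0
    )
    out["sum_variance"] = sum(v * (k - sa) ** 2 for k, v in psum.items())
    out["variance"] = var
    return out


def brute_glrlm(labels: np.ndarray, n_levels: int, angle: int, max_len: int) -> np.ndarray:
    """Run-length matrix by walking every lattice line voxel by voxel."""
    dr, dc = ANGLE_STEPS[angle]
    rows, cols = labels.shape
    # line starts: cells with no predecessor along (dr, dc)
    R = np.zeros((n_levels, max_len))
    for r0 in range(rows):
        for c0 in range(cols):
            pr, pc = r0 - dr, c0 - dc
            if 0 <= pr < rows and 0 <= pc < cols:
                continue  # not a line start
            run_val, run_len = 0, 0
            r, c = r0, c0
            while 0 <= r < rows and 0 <= c < cols:
                v = labels[r, c]
                if v == run_val and v > 0:
                    run_len += 1
                else:
                    if run_val > 0:
                        R[run_val - 1, run_len - 1] += 1
                    run_val, run_len = v, (1 if v > 0 else 0)
                r, c = r + dr, c + dc
            if run_val > 0:
                R[run_val - 1, run_len - 1] += 1
    return R


def brute_glrlm_features(R: np.ndarray) -> dict[str, float]:
    """The 13 run-length features by naive double summation."""
    ng, lmax = R.shape
    nr = R.sum()
    npix = sum(R[i, l] * (l + 1) for i in range(ng) for l in range(lmax))
    out = {}
    out["sre"] = sum(R[i, l] / (l + 1) ** 2 for i in range(ng) for l in range(lmax)) / nr
    out["lre"] = sum(R[i, l] * (l + 1) ** 2 for i in range(ng) for l in range(lmax)) / nr
    out["gln"] = sum(R[i, :].sum() ** 2 for i in range(ng)) / nr
    out["rln"] = sum(R[:, l].sum() ** 2 for l in range(lmax)) / nr
    out["rp"] = nr / npix
    out["lglre"] = sum(R[i, l] / (i + 1) ** 2 for i in range(ng) for l in range(lmax)) / nr
    out["hglre"] = sum(R[i, l] * (i + 1) ** 2 for i in range(ng) for l in range(lmax)) / nr
    out["srlgle"] = sum(
        R[i, l] / ((i + 1) ** 2 * (l + 1) ** 2) for i in range(ng) for l in range(lmax)
    ) / nr
    out["srhgle"] = sum(
        R[i, l] * (i + 1) ** 2 / (l + 1) ** 2 for i in range(ng) for l in range(lmax)
    ) / nr
    out["lrlgle"] = sum(
        R[i, l] * (l + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for l in range(lmax)
    ) / nr
    out["lrhgle"] = sum(
        R[i, l] * (i + 1) ** 2 * (l + 1) ** 2 for i in range(ng) for l in range(lmax)
    ) / nr
    mu_i = sum(R[i, l] / nr * (i + 1) for i in range(ng) for l in range(lmax))
    out["glv"] = sum(
        R[i, l] / nr * (i + 1 - mu_i) ** 2 for i in range(ng) for l in range(lmax)
    )
    mu_l = sum(R[i, l] / nr * (l + 1) for i in range(ng) for l in range(lmax))
    out["rlv"] = sum(
        R[i, l] / nr * (l + 1 - mu_l) ** 2 for i in range(ng) for l in range(lmax)
    )
    return out


def textbook_km(times, events):
    """Unweighted product-limit estimator: list of (time, S(t))."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    curve = []
    for t in sorted(set(times[events == 1])):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / n_at_risk
        curve.append((t, s))
    return curve
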