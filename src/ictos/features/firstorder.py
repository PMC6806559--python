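"""First-order intensity statistics of the ROI histogram.

Computed on the (normalized) intensities of all ROI voxels pooled across
slices. Moment features use population (1/n) moments; skewness is the Fisher
moment skewness m3 / m2^(3/2), zero by convention on a zero-variance ROI.
"""

from __future__ import annotations

import numpy as np


def intensity_features(
    vol, mask, n_bins: int = 32
) -> dict[str, float]:
    """The 19 first-order features of the ROI intensity distribution.

    ``entropy`` and ``uniformity`` are computed on a fixed-bin-count
    histogram (``n_bins`` over the ROI range), matching the discretization
    used for the texture matrices.
    """
    mask.check_aligned(vol)
    x = vol.voxels[mask.voxels].astype(float)
    if x.size < 3:
        raise ValueError("ROI must contain at least 3 voxels")
    n = x.size
    mean = float(x.mean())
    dev = x - mean
    m2 = float((dev**2).mean())
    m3 = float((dev**3).mean())
    m4 = float((dev**4).mean())
    sd = np.sqrt(m2)

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    if m2 > 0:
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
        cov = sd / mean if mean != 0 else 0.0
    else:
        skew, kurt, cov = 0.0, 0.0, 0.0  # degenerate constant ROI

    hist, _ = np.histogram(x, bins=n_bins)
    p = hist[hist > 0] / n

    return {
        "mean": mean,
        "median": float(p50),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "percentile10": float(p10),
        "percentile90": float(p90),
        "interquartile_range": float(p75 - p25),
        "variance": m2,
        "standard_deviation": float(sd),
        "mean_absolute_deviation": float(np.abs(dev).mean()),
        "robust_mean_absolute_deviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "root_mean_square": float(np.sqrt((x**2).mean())),
        "energy": float((x**2).sum()),
        "entropy": float(-(p * np.log2(p)).sum()),
        "uniformity": float((p**2).sum()),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "coefficient_of_variation": float(cov),
    }
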