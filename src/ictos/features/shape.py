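"""2D shape descriptors of the tumor outline.

Shape is measured on the axial slice with the largest ROI area (one value per
feature per ROI, consistent with the 2D convention of the rest of the
pipeline). Lengths are in millimetres via the in-plane spacing.
"""

from __future__ import annotations

import numpy as np
from skimage import measure


def shape_features(mask) -> dict[str, float]:
    """The 10 in-plane shape features on the maximum-area slice."""
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    areas = mask.voxels.reshape(mask.voxels.shape[0], -1).sum(axis=1)
    sl = mask.voxels[int(np.argmax(areas))]
    spacing = mask.in_plane_spacing

    labeled = measure.label(sl)
    props = max(measure.regionprops(labeled), key=lambda p: p.area)

    area = float(props.area) * spacing**2
    perimeter = float(props.perimeter) * spacing
    major = float(props.axis_major_length) * spacing
    minor = float(props.axis_minor_length) * spacing
    max_diam = float(props.feret_diameter_max) * spacing

    return {
        "area_mm2": area,
        "perimeter_mm": perimeter,
        "perimeter_to_area": perimeter / area if area > 0 else 0.0,
        "major_axis_mm": major,
        "minor_axis_mm": minor,
        "elongation": minor / major if major > 0 else 1.0,
        "circularity": (
            4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 1.0
        ),
        "max_diameter_mm": max_diam,
        "eccentricity": float(props.eccentricity),
        "aspect_ratio": major / minor if minor > 0 else float(sl.sum()),
    }
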