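"""The feature catalogue: names, families, offsets.

Per ROI the catalogue is 19 first-order intensity features, 10 2D shape
features, 24 GLCM features at 8 offsets (4 directions x 2 distances, reported
per offset, not averaged) and 13 GLRLM features at 4 directions:
19 + 10 + 192 + 52 = 273. Per patient, the three sequences give 3 x 273 = 819.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

INTENSITY_FEATURES = [
    "mean", "median", "minimum", "maximum", "range",
    "percentile10", "percentile90", "interquartile_range",
    "variance", "standard_deviation",
    "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "root_mean_square", "energy", "entropy", "uniformity",
    "skewness", "kurtosis", "coefficient_of_variation",
]

SHAPE_FEATURES = [
    "area_mm2", "perimeter_mm", "perimeter_to_area",
    "major_axis_mm", "minor_axis_mm", "elongation", "circularity",
    "max_diameter_mm", "eccentricity", "aspect_ratio",
]

GLCM_FEATURES = [
    "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "joint_energy",
    "joint_entropy", "imc1", "imc2", "inverse_difference",
    "inverse_difference_normalized", "inverse_difference_moment",
    "inverse_difference_moment_normalized", "inverse_variance",
    "maximum_probability", "sum_average", "sum_entropy", "sum_variance",
    "variance",
]

GLRLM_FEATURES = [
    "sre", "lre", "gln", "rln", "rp",
    "lglre", "hglre", "srlgle", "srhgle", "lrlgle", "lrhgle",
    "glv", "rlv",
]

ANGLES = (0, 45, 90, 135)
DISTANCES = (1, 2)
FEATURES_PER_ROI = 273
FEATURES_PER_PATIENT = 819


@dataclass
class FeatureCatalogue:
    """Ordered names of the per-ROI feature set."""

    angles: tuple[int, ...] = ANGLES
    distances: tuple[int, ...] = DISTANCES
    n_bins: int = 32
    names: list[str] = field(init=False)
    families: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        names: list[str] = []
        families: dict[str, str] = {}
        for f in INTENSITY_FEATURES:
            name = f"firstorder_{f}"
            names.append(name)
            families[name] = "intensity"
        for f in SHAPE_FEATURES:
            name = f"shape_{f}"
            names.append(name)
            families[name] = "shape"
        for d in self.distances:
            for a in self.angles:
                for f in GLCM_FEATURES:
                    name = f"glcm_{f}_d{d}_a{a}"
                    names.append(name)
                    families[name] = "glcm"
        for a in self.angles:
            for f in GLRLM_FEATURES:
                name = f"glrlm_{f}_a{a}"
                names.append(name)
                families[name] = "glrlm"
        self.names = names
        self.families = families
        assert len(names) == FEATURES_PER_ROI, (
            f"catalogue has {len(names)} features per ROI, expected "
            f"{FEATURES_PER_ROI}"
        )

    @property
    def patient_names(self) -> list[str]:
        """819 per-patient names: per-ROI names prefixed by sequence."""
        out = [f"{seq}_{n}" for seq in ("T1", "T2", "T1C") for n in self.names]
        assert len(out) == FEATURES_PER_PATIENT
        return out

    def to_yaml(self, path) -> None:
        payload = {
            "angles": list(self.angles),
            "distances": list(self.distances),
            "n_bins": self.n_bins,
            "intensity": INTENSITY_FEATURES,
            "shape": SHAPE_FEATURES,
            "glcm": GLCM_FEATURES,
            "glrlm": GLRLM_FEATURES,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def default_catalogue() -> FeatureCatalogue:
    return FeatureCatalogue()
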