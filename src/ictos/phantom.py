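"""Synthetic texture phantoms with controllable radiomic structure.

Each phantom is three co-registered axial stacks (T1, T2, contrast-enhanced
T1) containing an elliptical "body" and a cylindrical tumor ROI. Three knobs
steer the three feature axes the benefit model lives on:

* ``target_skew`` — the ROI noise is drawn from a skew-normal whose shape
  parameter follows the knob, and the sign balance of the extreme "anchor"
  patches is tilted so the minority mode sits on the heavy-tail side; the
  intensity-histogram skewness rises monotonically with the knob (in
  expectation).
* ``heterogeneity`` — fixed-amplitude (±5) anchor patches cover a growing
  fraction of the ROI, moving histogram mass to the extreme gray levels at a
  stable min-max range; after fixed-bin-count discretization this widens the
  co-occurrence gray-level distribution, i.e. raises GLCM joint variance.
* ``run_structure`` — a fixed fraction of the ROI is covered by noise-free
  constant plateaus along the row direction whose length and amplitude grow
  with the knob, creating long same-level runs at mid-extreme gray levels
  and raising long-run/high-gray run-length emphasis.

Texture is full strength on T1C and attenuated on T1/T2, mimicking a lesion
whose texture is most expressed on the contrast-enhanced sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .images import MRVolume, ROIMask, dice

__all__ = ["TexturePhantomSpec", "generate_phantom", "perturb_mask", "dice"]

# structural amplitude per sequence, relative to T1C
_SEQ_BASE = {"T1": 60.0, "T2": 80.0, "T1C": 100.0}
_SEQ_ATTENUATION = {"T1": 0.4, "T2": 0.7, "T1C": 1.0}
_BODY_OFFSET = 0.0  # body tissue at the lesion's base level (mask-defined ROI)
_BODY_NOISE_SD = 1.5
_LESION_CONTRAST_SD = 2.0  # per-phantom lesion-vs-body intensity offset

_PATCH_SIZE = 2  # voxels, side of heterogeneity anchor patches
_PATCH_AMP = 5.0  # intensity units, fixed anchor amplitude
_PATCH_BASE_FRACTION = 0.05  # anchor coverage at heterogeneity 0
_PATCH_FRACTION_PER_UNIT = 0.18  # extra coverage per unit heterogeneity
_PATCH_SIGN_TILT = 0.8  # logit tilt of anchor sign per unit target_skew
_RUN_AMP_MAX = 3.5  # intensity units, saturating amplitude of run plateaus
_RUN_PLATEAU_FRACTION = 0.3  # expected ROI fraction covered by run plateaus
_SKEWNORM_SHAPE_PER_UNIT = 4.0  # skew-normal shape per unit target_skew
_NOISE_CLIP = 2.5  # SD units; keeps the ROI range anchor-dominated


@dataclass
class TexturePhantomSpec:
    """Parameters of one synthetic tumor phantom."""

    grid_shape: tuple[int, int, int] = (3, 48, 48)
    roi_radius: int = 10  # voxels, in-plane
    target_skew: float = 0.0
    heterogeneity: float = 1.0  # >= 0
    run_structure: float = 1.0  # >= 0
    noise_sd: float = 2.0  # intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        s, r, c = self.grid_shape
        if min(s, r, c) <= 0:
            raise ValueError("grid_shape must be positive")
        if self.roi_radius <= 0:
            raise ValueError("roi_radius must be positive")
        # the ROI disk must sit strictly inside the body ellipse
        if self.roi_radius + 2 > 0.45 * min(r, c):
            raise ValueError(
                f"roi_radius {self.roi_radius} too large for in-plane grid "
                f"{(r, c)}: the ROI must fit inside the body"
            )
        if self.heterogeneity < 0 or self.run_structure < 0:
            raise ValueError("heterogeneity and run_structure must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _standardized_skewnorm(rng: np.random.Generator, shape: float, size) -> np.ndarray:
    """Skew-normal draws rescaled to mean 0, SD 1."""
    if shape == 0.0:
        return np.clip(rng.standard_normal(size), -_NOISE_CLIP, _NOISE_CLIP)
    delta = shape / np.sqrt(1.0 + shape * shape)
    mean = delta * np.sqrt(2.0 / np.pi)
    sd = np.sqrt(1.0 - 2.0 * delta * delta / np.pi)
    draws = stats.skewnorm.rvs(shape, size=size, random_state=rng)
    out = (draws - mean) / sd
    # bound the tails so the ROI min/max (hence the fixed-bin gray-level
    # grid) is set by the plateau/patch structure, not by single outliers
    return np.clip(out, -_NOISE_CLIP, _NOISE_CLIP)


def _block_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    block_rc: tuple[int, int],
    values: str,
) -> np.ndarray:
    """Per-slice field constant on (block_rows x block_cols) tiles."""
    s, r, c = shape
    br, bc = block_rc
    nr, nc = -(-r // br), -(-c // bc)
    if values == "pm1":
        blocks = rng.choice([-1.0, 1.0], size=(s, nr, nc))
    else:
        blocks = rng.standard_normal((s, nr, nc))
    field = np.repeat(np.repeat(blocks, br, axis=1), bc, axis=2)
    return field[:, :r, :c]


def generate_phantom(spec: TexturePhantomSpec) -> tuple[dict[str, MRVolume], ROIMask]:
    """Build the three-sequence phantom and its tumor mask.

    Returns a dict keyed by sequence label and the shared ROI mask. The same
    seed reproduces the phantom bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    s, r, c = spec.grid_shape
    rows, cols = np.mgrid[0:r, 0:c]
    cr, cc = (r - 1) / 2.0, (c - 1) / 2.0

    body2d = ((rows - cr) / (0.48 * r)) ** 2 + ((cols - cc) / (0.48 * c)) ** 2 <= 1.0
    roi2d = (rows - cr) ** 2 + (cols - cc) ** 2 <= spec.roi_radius**2
    body = np.broadcast_to(body2d, (s, r, c)).copy()
    roi = np.broadcast_to(roi2d, (s, r, c)).copy()

    # structural fields shared across sequences (co-registered texture).
    # anchor patches: fixed +-5 amplitude, coverage grows with heterogeneity,
    # sign balance tilted by target_skew (minority mode on the heavy side)
    patch_gate = _block_field(rng, (s, r, c), (_PATCH_SIZE, _PATCH_SIZE), "normal")
    if spec.heterogeneity > 0:
        frac = min(
            _PATCH_BASE_FRACTION + _PATCH_FRACTION_PER_UNIT * spec.heterogeneity, 0.6
        )
    else:
        frac = 0.0
    patch_on = patch_gate < np.quantile(np.unique(patch_gate), frac)
    p_plus = 1.0 / (1.0 + np.exp(_PATCH_SIGN_TILT * spec.target_skew))
    patch_u = _block_field(rng, (s, r, c), (_PATCH_SIZE, _PATCH_SIZE), "normal")
    patch_sign = np.where(
        patch_u < np.quantile(np.unique(patch_u), p_plus), 1.0, -1.0
    )
    # run plateaus: noise-free, fixed coverage, length and amplitude grow
    # with run_structure
    run_len = 1 + int(round(2.0 * spec.run_structure))
    run_sign = _block_field(rng, (s, r, c), (1, run_len), "pm1")
    run_gate = _block_field(rng, (s, r, c), (1, run_len), "normal")
    plateau = run_gate < np.quantile(np.unique(run_gate), _RUN_PLATEAU_FRACTION)
    run_amp = _RUN_AMP_MAX * (1.0 - np.exp(-1.5 * spec.run_structure))
    if spec.run_structure == 0:
        plateau = np.zeros_like(plateau)
    plateau = plateau & ~patch_on  # anchors take precedence

    shape_param = _SKEWNORM_SHAPE_PER_UNIT * spec.target_skew
    # patient-specific lesion contrast: distinguishes subjects on first-order
    # location features the way real lesions differ in enhancement
    contrast = rng.normal(0.0, _LESION_CONTRAST_SD)
    volumes: dict[str, MRVolume] = {}
    for label in ("T1", "T2", "T1C"):
        vox = np.zeros((s, r, c))
        body_noise = rng.standard_normal((s, r, c))
        vox[body] = (
            _SEQ_BASE[label] + _BODY_OFFSET + _BODY_NOISE_SD * body_noise[body]
        )
        roi_noise = _standardized_skewnorm(rng, shape_param, (s, r, c))
        att = _SEQ_ATTENUATION[label]
        texture = np.where(
            patch_on,
            att * _PATCH_AMP * patch_sign,
            np.where(
                plateau,
                att * run_amp * run_sign,
                spec.noise_sd * roi_noise,
            ),
        )
        vox[roi] = _SEQ_BASE[label] + att * contrast + texture[roi]
        volumes[label] = MRVolume(sequence_label=label, voxels=vox)
    mask = ROIMask(voxels=roi)
    return volumes, mask


def perturb_mask(mask: ROIMask, jitter_vox: int, seed: int = 0) -> ROIMask:
    """Emulate a re-segmentation: random in-plane shift plus dilation/erosion.

    ``jitter_vox`` bounds both the shift (per in-plane axis) and the number of
    morphological iterations; 0 returns the mask unchanged. Raises if the
    perturbed mask would be empty or no longer overlap the original.
    """
    if mask.n_voxels == 0:
        raise ValueError("cannot perturb an empty mask")
    if jitter_vox < 0:
        raise ValueError("jitter_vox must be >= 0")
    if jitter_vox == 0:
        return ROIMask(
            voxels=mask.voxels.copy(),
            in_plane_spacing=mask.in_plane_spacing,
            slice_thickness=mask.slice_thickness,
        )
    rng = np.random.default_rng(seed)
    shift = (0, *rng.integers(-jitter_vox, jitter_vox + 1, size=2))
    vox = ndimage.shift(mask.voxels.astype(float), shift, order=0) > 0.5
    n_iter = int(rng.integers(0, jitter_vox + 1))
    if n_iter:
        struct = np.zeros((3, 3, 3), dtype=bool)
        struct[1] = ndimage.generate_binary_structure(2, 1)  # in-plane only
        if rng.random() < 0.5:
            vox = ndimage.binary_dilation(vox, structure=struct, iterations=n_iter)
        else:
            vox = ndimage.binary_erosion(vox, structure=struct, iterations=n_iter)
    if not vox.any():
        raise ValueError("perturbation emptied the mask; reduce jitter_vox")
    out = ROIMask(
        voxels=vox,
        in_plane_spacing=mask.in_plane_spacing,
        slice_thickness=mask.slice_thickness,
    )
    if dice(mask, out) == 0.0:
        raise ValueError("perturbed mask no longer overlaps the original")
    return out
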