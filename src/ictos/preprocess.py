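"""Preprocessing before feature extraction.

Three steps, applied per volume: in-plane resampling to a common grid,
whole-volume intensity z-scoring over in-body (nonzero) voxels, and
fixed-bin-count gray-level discretization inside the ROI. All texture work
downstream is 2D (per axial slice), so resampling changes only rows/cols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import MRVolume, ROIMask


@dataclass
class PreprocessConfig:
    target_spacing_mm: float = 1.0
    n_bins: int = 32
    normalization: str = "zscore"  # "zscore" | "none"

    def __post_init__(self) -> None:
        if self.target_spacing_mm <= 0:
            raise ValueError("target_spacing_mm must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.normalization not in ("zscore", "none"):
            raise ValueError("normalization must be 'zscore' or 'none'")


@dataclass
class GrayLevelMap:
    """Discretized gray levels 1..n_bins inside the ROI, 0 outside."""

    labels: np.ndarray  # int array, 0 outside ROI
    n_bins: int
    bin_edges: np.ndarray
    degenerate: bool = False  # constant ROI collapsed to a single level
    in_plane_spacing: float = 1.0

    @property
    def roi_voxel_count(self) -> int:
        return int((self.labels > 0).sum())


def _resample_slicewise(stack: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Resample rows/cols of every slice with pixel-center alignment."""
    s, r, c = stack.shape
    new_r = max(int(round(r * factor)), 1)
    new_c = max(int(round(c * factor)), 1)
    # output pixel centers mapped into input index space
    rr = (np.arange(new_r) + 0.5) / factor - 0.5
    cc = (np.arange(new_c) + 0.5) / factor - 0.5
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    out = np.empty((s, new_r, new_c), dtype=float)
    for k in range(s):
        out[k] = ndimage.map_coordinates(
            stack[k], [grid_r, grid_c], order=order, mode="nearest"
        )
    return out


def resample_inplane(
    vol: MRVolume, mask: ROIMask, target_spacing_mm: float
) -> tuple[MRVolume, ROIMask]:
    """Resample image (bilinear) and mask (nearest) to the target spacing.

    Slice count and slice thickness are unchanged; identity spacing is a
    no-op so already-conformant inputs pass through untouched.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    mask.check_aligned(vol)
    if np.isclose(target_spacing_mm, vol.in_plane_spacing):
        return vol, mask
    factor = vol.in_plane_spacing / target_spacing_mm
    new_vox = _resample_slicewise(vol.voxels, factor, order=1)
    new_mask = _resample_slicewise(mask.voxels.astype(float), factor, order=0) > 0.5
    out_vol = MRVolume(
        sequence_label=vol.sequence_label,
        voxels=new_vox,
        in_plane_spacing=target_spacing_mm,
        slice_thickness=vol.slice_thickness,
    )
    out_mask = ROIMask(
        voxels=new_mask,
        in_plane_spacing=target_spacing_mm,
        slice_thickness=vol.slice_thickness,
    )
    return out_vol, out_mask


def normalize_intensity(vol: MRVolume) -> MRVolume:
    """Z-score the volume over its in-body (nonzero) voxels.

    Controls scanner/vendor intensity scale: output in-body voxels have mean
    0 and SD 1. Background (exact zeros) is left at zero. A constant body is
    rejected — there is no scale to normalize.
    """
    vox = vol.voxels
    body = vox != 0
    if not body.any():
        raise ValueError("volume has no nonzero voxels to normalize over")
    vals = vox[body]
    sd = float(vals.std())
    if sd == 0.0:
        raise ValueError("zero variance: constant volume cannot be z-scored")
    out = np.zeros_like(vox, dtype=float)
    out[body] = (vals - vals.mean()) / sd
    return vol.with_voxels(out)


def discretize(vol: MRVolume, mask: ROIMask, n_bins: int = 32) -> GrayLevelMap:
    """Fixed-bin-count discretization of ROI intensities.

    The ROI [min, max] range is split into ``n_bins`` equal bins; the minimum
    maps to level 1 and the maximum to level ``n_bins``. A constant ROI maps
    everything to level 1 and is flagged degenerate.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask.check_aligned(vol)
    roi = mask.voxels
    if not roi.any():
        raise ValueError("mask is empty")
    vals = vol.voxels[roi]
    lo, hi = float(vals.min()), float(vals.max())
    labels = np.zeros(vol.voxels.shape, dtype=np.int32)
    if hi == lo:
        labels[roi] = 1
        edges = np.linspace(lo, lo + 1.0, n_bins + 1)
        return GrayLevelMap(labels, n_bins, edges, degenerate=True,
                            in_plane_spacing=vol.in_plane_spacing)
    width = (hi - lo) / n_bins
    lab = np.floor((vals - lo) / width).astype(np.int32) + 1
    np.clip(lab, 1, n_bins, out=lab)
    labels[roi] = lab
    edges = np.linspace(lo, hi, n_bins + 1)
    return GrayLevelMap(labels, n_bins, edges, degenerate=False,
                        in_plane_spacing=vol.in_plane_spacing)
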