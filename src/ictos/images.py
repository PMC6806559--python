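"""Image containers and NIfTI I/O.

Volumes are stored as (slices, rows, cols) arrays with isotropic in-plane
spacing; all texture analysis in this package is per axial slice, so only the
in-plane spacing enters feature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

SEQUENCE_LABELS = ("T1", "T2", "T1C")


@dataclass
class MRVolume:
    """One MR sequence: an axial stack plus its voxel geometry."""

    sequence_label: str
    voxels: np.ndarray  # (slices, rows, cols), float
    in_plane_spacing: float = 1.0  # mm, isotropic within slice
    slice_thickness: float = 5.0  # mm

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a (slices, rows, cols) array")
        if self.in_plane_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray, **kw) -> "MRVolume":
        return replace(self, voxels=voxels, **kw)


@dataclass
class ROIMask:
    """Binary tumor mask aligned voxel-for-voxel with its MRVolume."""

    voxels: np.ndarray  # (slices, rows, cols), bool
    in_plane_spacing: float = 1.0
    slice_thickness: float = 5.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a (slices, rows, cols) array")
        if self.in_plane_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_aligned(self, vol: MRVolume) -> None:
        if self.voxels.shape != vol.voxels.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match volume "
                f"shape {vol.voxels.shape}"
            )


@dataclass
class PatientScan:
    """The three co-registered sequences and the shared tumor mask."""

    patient_id: str
    volumes: dict = field(default_factory=dict)  # label -> MRVolume
    mask: ROIMask | None = None

    def sequence(self, label: str) -> MRVolume:
        if label not in self.volumes:
            raise KeyError(f"sequence {label!r} missing for {self.patient_id}")
        return self.volumes[label]


def _affine(in_plane: float, thickness: float) -> np.ndarray:
    return np.diag([in_plane, in_plane, thickness, 1.0])


def save_volume_nifti(vol: MRVolume, path: str | Path) -> None:
    """Write as .nii/.nii.gz; axial slices become the third NIfTI axis."""
    data = np.transpose(vol.voxels, (2, 1, 0))
    img = nib.Nifti1Image(data, _affine(vol.in_plane_spacing, vol.slice_thickness))
    nib.save(img, str(path))


def save_mask_nifti(mask: ROIMask, path: str | Path) -> None:
    data = np.transpose(mask.voxels.astype(np.uint8), (2, 1, 0))
    img = nib.Nifti1Image(data, _affine(mask.in_plane_spacing, mask.slice_thickness))
    nib.save(img, str(path))


def load_volume_nifti(path: str | Path, sequence_label: str) -> MRVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)).astype(float)
    return MRVolume(
        sequence_label=sequence_label,
        voxels=data,
        in_plane_spacing=float(zooms[0]),
        slice_thickness=float(zooms[2]),
    )


def load_mask_nifti(path: str | Path) -> ROIMask:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)) > 0
    return ROIMask(
        voxels=data,
        in_plane_spacing=float(zooms[0]),
        slice_thickness=float(zooms[2]),
    )


def dice(a: ROIMask | np.ndarray, b: ROIMask | np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    va = a.voxels if isinstance(a, ROIMask) else np.asarray(a, dtype=bool)
    vb = b.voxels if isinstance(b, ROIMask) else np.asarray(b, dtype=bool)
    if va.shape != vb.shape:
        raise ValueError("masks must share a shape")
    denom = va.sum() + vb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(va, vb).sum()) / float(denom)
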