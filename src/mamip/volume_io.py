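"""Reading, writing, resampling and windowing of 3D PET/CT volumes.

Canonical axis convention
-------------------------
All volumes in this package are stored with axes ordered ``(x, y, z)`` where

* ``x`` runs left -> right,
* ``y`` runs posterior -> anterior,
* ``z`` runs inferior -> superior,

i.e. the RAS+ orientation that :func:`nibabel.as_closest_canonical` produces.
Files are reoriented into this convention at load time regardless of their
on-disk orientation codes, so every downstream rotation/projection axis is
defined against a single frame. Voxel indices are 0-based and all index
boxes are half-open ``[lo, hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "ImageVolume",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "clip_hu",
    "BONE_WINDOW_HU",
]

#: Hounsfield window bracketing hard (bone) tissue, used for the CT
#: projections that guide the anatomical head-and-neck crop.
BONE_WINDOW_HU = (700.0, 2000.0)


@dataclass
class ImageVolume:
    """A 3D voxel grid with physical metadata.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Voxel values in the canonical (x, y, z) axis order.
    spacing_mm : tuple of float
        Voxel size along (x, y, z); strictly positive.
    origin_mm : tuple of float
        Physical coordinate of the center of voxel (0, 0, 0).
    modality : str
        Either ``"PET"`` or ``"CT"``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "PET"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must all be finite")
        if self.modality not in ("PET", "CT"):
            raise ValueError(f"modality must be 'PET' or 'CT', got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "ImageVolume":
        return replace(self, voxels=self.voxels.copy())


def read_volume(path, modality: str = "PET") -> ImageVolume:
    """Read a NIfTI volume and reorient it into the canonical axis order.

    The on-disk orientation codes are honoured: axes are permuted/flipped
    into RAS+ so that callers always see the convention documented in this
    module. Spacing and origin are taken from the (reoriented) header.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"could not read NIfTI volume from {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    voxels = np.asarray(img.dataobj, dtype=np.float32)
    if voxels.ndim != 3:
        raise IOError(f"{path} does not contain a 3D volume (shape {voxels.shape})")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise IOError(f"{path} has missing or invalid voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(voxels, tuple(float(z) for z in zooms), origin, modality)


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI with a diagonal RAS+ affine."""
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))


def resample_isotropic(
    vol: ImageVolume, target_mm: float = 1.0, spline_order: int = 3
) -> ImageVolume:
    """Resample a volume onto an isotropic grid with spline interpolation.

    The output covers the same physical extent (output size is
    ``floor(extent_mm / target_mm)`` per axis, minimum 1) and boundary
    samples use edge replication. The default third-order spline matches
    common practice for harmonizing multi-center PET/CT voxel sizes.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    if any(n < 2 for n in vol.shape):
        raise ValueError(f"cannot resample degenerate volume of shape {vol.shape}")
    spacing = np.asarray(vol.spacing_mm)
    extent = np.asarray(vol.shape) * spacing
    out_shape = np.maximum(np.floor(extent / target_mm).astype(int), 1)
    if np.allclose(spacing, target_mm) and tuple(out_shape) == vol.shape:
        return vol.copy()
    # Output voxel j sits at physical offset j*target from voxel 0, i.e. at
    # fractional input index j*target/spacing along each axis.
    axes_idx = [np.arange(n) * target_mm / s for n, s in zip(out_shape, spacing)]
    grid = np.meshgrid(*axes_idx, indexing="ij")
    coords = np.stack(grid)
    out = ndi.map_coordinates(
        np.asarray(vol.voxels, dtype=np.float64),
        coords,
        order=spline_order,
        mode="nearest",
    )
    return ImageVolume(
        out.astype(np.float32),
        (target_mm, target_mm, target_mm),
        vol.origin_mm,
        vol.modality,
    )


def clip_hu(
    vol: ImageVolume,
    lo: float = BONE_WINDOW_HU[0],
    hi: float = BONE_WINDOW_HU[1],
    mode: str = "clamp",
) -> ImageVolume:
    """Window a CT volume to a Hounsfield range.

    ``mode="clamp"`` (default) saturates both tails to [lo, hi], preserving
    bone as a solid bright region against a background pinned at ``lo`` —
    the behaviour the bone-guided projections rely on. ``mode="zero"``
    instead maps every out-of-window voxel to ``lo``.
    """
    if vol.modality != "CT":
        raise ValueError(f"clip_hu expects a CT volume, got modality {vol.modality!r}")
    if lo >= hi:
        raise ValueError(f"require lo < hi, got lo={lo}, hi={hi}")
    if mode == "clamp":
        out = np.clip(vol.voxels, lo, hi)
    elif mode == "zero":
        out = np.where((vol.voxels >= lo) & (vol.voxels <= hi), vol.voxels, lo)
    else:
        raise ValueError(f"unknown clip mode {mode!r}")
    return ImageVolume(out, vol.spacing_mm, vol.origin_mm, vol.modality)
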