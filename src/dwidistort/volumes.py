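"""Volumetric containers and NIfTI-1 I/O.

Arrays are indexed ``(slice k, row j, column i)`` with spacing ``(dz, dy, dx)``
in mm.  The fixed anatomical convention is:

* slice index increases apex -> base (toward Superior),
* row index increases anterior -> posterior (toward Posterior),
* column index increases patient-right -> patient-left (toward Left),

i.e. axis codes ``("S", "P", "L")`` in nibabel's terminology.  Volumes read
from disk are reoriented to this convention (the applied permutation/flips are
logged), so "posterior" always means increasing row index, for supine and
prone acquisitions alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import orientations as nio

from .errors import LabelError, VolumeFormatError

logger = logging.getLogger(__name__)

#: Anatomical axis codes of the in-memory array axes (k, j, i).
AXIS_CODES = ("S", "P", "L")

#: Organ label encoding used throughout the package.
LABELS = {"background": 0, "prostate": 1, "rectum": 2, "air": 3}
BACKGROUND, PROSTATE, RECTUM, AIR = 0, 1, 2, 3
_VALID_LABELS = frozenset(LABELS.values())


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive mm values, got {spacing}")
    return spacing


@dataclass
class LabelVolume:
    """3D organ/air label map on an anisotropic voxel grid.

    Parameters
    ----------
    voxels : ndarray of int, shape (nk, nj, ni)
        Label values drawn from :data:`LABELS`.
    spacing : (dz, dy, dx)
        Voxel spacing in mm along (slice, row, column).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise LabelError(f"label volume must hold integers, got {self.voxels.dtype}")
        present = set(np.unique(self.voxels).tolist())
        if not present <= _VALID_LABELS:
            raise LabelError(f"invalid label values {sorted(present - _VALID_LABELS)}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.voxels == label))

    def binary(self, label: int) -> np.ndarray:
        """Boolean mask of one label."""
        return self.voxels == label


@dataclass
class IntensityVolume:
    """3D scalar signal volume sharing the grid convention of :class:`LabelVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = field(default=(3.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensity volume contains non-finite values")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def _affine_for_convention(spacing) -> np.ndarray:
    """RAS affine whose array axes follow the (S, P, L) convention."""
    dz, dy, dx = spacing
    aff = np.zeros((4, 4))
    aff[0, 2] = -dx  # column index -> Left == -x(RAS)
    aff[1, 1] = -dy  # row index -> Posterior == -y(RAS)
    aff[2, 0] = dz   # slice index -> Superior == +z(RAS)
    aff[3, 3] = 1.0
    return aff


def _load_normalized(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read {path!s} as NIfTI-1: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path!s}: expected a 3D volume, got shape {data.shape}")
    src_ornt = nio.io_orientation(img.affine)
    dst_ornt = nio.axcodes2ornt(AXIS_CODES)
    xform = nio.ornt_transform(src_ornt, dst_ornt)
    if not np.array_equal(xform, [[0, 1], [1, 1], [2, 1]]):
        logger.info("reorienting %s with axis transform %s", path, xform.tolist())
    data = nio.apply_orientation(data, xform)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    spacing = np.empty(3)
    for old_axis in range(3):
        spacing[int(xform[old_axis, 0])] = zooms[old_axis]
    return data, tuple(spacing)


def read_label_volume(path) -> LabelVolume:
    """Read a NIfTI-1 label volume, normalizing orientation to (S, P, L)."""
    data, spacing = _load_normalized(path)
    if np.issubdtype(data.dtype, np.floating):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise LabelError(f"{path!s}: label volume contains non-integer voxel values")
        data = rounded.astype(np.int16)
    return LabelVolume(data.astype(np.int16), spacing)


def read_intensity_volume(path) -> IntensityVolume:
    """Read a NIfTI-1 scalar volume, normalizing orientation to (S, P, L)."""
    data, spacing = _load_normalized(path)
    return IntensityVolume(data.astype(float), spacing)


def write_label_volume(vol: LabelVolume, path) -> None:
    img = nib.Nifti1Image(vol.voxels.astype(np.uint8), _affine_for_convention(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_intensity_volume(vol: IntensityVolume, path) -> None:
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), _affine_for_convention(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


__all__ = [
    "AXIS_CODES",
    "LABELS",
    "BACKGROUND",
    "PROSTATE",
    "RECTUM",
    "AIR",
    "LabelVolume",
    "IntensityVolume",
    "read_label_volume",
    "read_intensity_volume",
    "write_label_volume",
    "write_intensity_volume",
]
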