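"""Rectal air segmentation and prostate-proximity volumes (``Rectal Air_prox``).

Air is dark on the contrast-enhanced reference image; it is segmented inside
the rectum outline by a signal-intensity threshold and split into connected
pockets.  The clinically relevant quantity is the volume of air lying within
20 mm of the prostate surface, computed with an anisotropic-spacing-aware
Euclidean distance transform (equivalent to dilating the prostate volume by
the proximity distance and intersecting with air).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ValidationError
from .volumes import AIR, IntensityVolume, LabelVolume

#: Default proximity distance (mm) deemed liable to cause susceptibility artefact.
DEFAULT_PROXIMITY_MM = 20.0
#: Percentile of the full-volume intensity distribution used by the automatic
#: air threshold (air signal is far below tissue on T1/DCE).
AUTO_THRESHOLD_PERCENTILE = 2.5


@dataclass
class AirMeasure:
    """Total and prostate-proximal rectal air volumes in cm^3."""

    total_cm3: float
    proximal_cm3: float
    distance_mm: float = DEFAULT_PROXIMITY_MM
    n_pockets: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.proximal_cm3 <= self.total_cm3 + 1e-9:
            raise ValueError("proximal volume must lie within [0, total]")

    def to_dict(self) -> dict:
        return {
            "total_cm3": self.total_cm3,
            "proximal_cm3": self.proximal_cm3,
            "distance_mm": self.distance_mm,
            "n_pockets": self.n_pockets,
        }


def auto_threshold(intensity: IntensityVolume,
                   percentile: float = AUTO_THRESHOLD_PERCENTILE) -> float:
    """Low-percentile intensity threshold separating air from tissue."""
    return float(np.percentile(intensity.voxels, percentile))


def segment_air(intensity: IntensityVolume, rectum_mask: LabelVolume,
                threshold: float | str = "auto",
                min_voxels: int = 5) -> LabelVolume:
    """Threshold-based air segmentation restricted to the rectum outline.

    Voxels inside the rectum with intensity strictly below ``threshold`` are
    labelled air; connected components (face connectivity) smaller than
    ``min_voxels`` are discarded as noise.  ``threshold='auto'`` uses the
    2.5th percentile of the volume's intensity distribution.
    """
    if intensity.shape != rectum_mask.shape:
        raise ValueError("intensity and rectum mask must share the same grid")
    if threshold == "auto":
        threshold = auto_threshold(intensity)
    threshold = float(threshold)
    lo, hi = float(intensity.voxels.min()), float(intensity.voxels.max())
    if not lo <= threshold <= hi:
        warnings.warn(
            f"threshold {threshold} outside observed intensity range [{lo}, {hi}]",
            RuntimeWarning, stacklevel=2)
    raw = (intensity.voxels < threshold) & (rectum_mask.voxels > 0)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labelled, n = ndimage.label(raw, structure=structure)
    counts = np.bincount(labelled.ravel(), minlength=n + 1)
    keep = (labelled > 0) & (counts[labelled] >= min_voxels)
    return LabelVolume(np.where(keep, AIR, 0).astype(np.int16), rectum_mask.spacing)


def count_pockets(air_mask: LabelVolume) -> int:
    structure = ndimage.generate_binary_structure(3, 1)
    _, n = ndimage.label(air_mask.voxels > 0, structure=structure)
    return int(n)


def air_proximity_volume(air_mask: LabelVolume, prostate_mask: LabelVolume,
                         distance_mm: float = DEFAULT_PROXIMITY_MM) -> AirMeasure:
    """Total air volume and the portion within ``distance_mm`` of the prostate.

    The proximity test uses the exact Euclidean distance from each air voxel
    to the nearest prostate voxel, honouring anisotropic spacing; volumes are
    voxel counts times the voxel volume, reported in cm^3.
    """
    if air_mask.shape != prostate_mask.shape:
        raise ValueError("air and prostate masks must share the same grid")
    if air_mask.spacing != prostate_mask.spacing:
        raise ValueError("air and prostate masks must share the same spacing")
    prostate = prostate_mask.voxels > 0
    if not prostate.any():
        raise DegenerateInputError("prostate mask is empty")
    air = air_mask.voxels > 0
    vox_cm3 = air_mask.voxel_volume_mm3 / 1000.0
    dist = ndimage.distance_transform_edt(~prostate, sampling=air_mask.spacing)
    proximal = air & (dist <= distance_mm)
    return AirMeasure(
        total_cm3=float(air.sum() * vox_cm3),
        proximal_cm3=float(proximal.sum() * vox_cm3),
        distance_mm=float(distance_mm),
        n_pockets=count_pockets(air_mask),
    )


def dichotomize(scores, cutoff: int = 4) -> np.ndarray:
    """Dichotomize 5-point rectal-air Likert scores: 1 if score >= cutoff.

    Scores >= 4 represent clinically significant ("appreciable") rectal air.
    """
    arr = np.asarray(scores)
    if arr.size and (not np.issubdtype(arr.dtype, np.number)
                     or (arr < 1).any() or (arr > 5).any()
                     or not np.allclose(arr, np.rint(arr))):
        raise ValidationError("Likert scores must be integers in 1..5")
    return (arr >= cutoff).astype(int)


__all__ = [
    "DEFAULT_PROXIMITY_MM",
    "AUTO_THRESHOLD_PERCENTILE",
    "AirMeasure",
    "auto_threshold",
    "segment_air",
    "count_pockets",
    "air_proximity_volume",
    "dichotomize",
]
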