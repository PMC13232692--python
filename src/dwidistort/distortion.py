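"""Polar radial distortion between ADC and reference prostate contours.

Pipeline steps 3-5: for each paired slice, both outlines are sampled in polar
coordinates at 1-degree increments about a common origin (the reference
contour's area centroid), the signed radial residual dr(theta) = r_ADC - r_ref
is recorded, and the residuals are reduced to a whole-gland RMS and a
posterior-half RMS (``Distortion_post``).

Angle convention: 0 deg = +x (patient left), counter-clockwise in the
(x, y = posterior) plane, so 90 deg points posterior; the posterior half is
theta in [1, 180] degrees (exactly 180 of the 360 samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .contours import ContourSet, points_in_polygon, polygon_centroid, _as_open_polygon
from .errors import ContractError, DegenerateInputError, EmptyPairingError
from .registration import MaskTransform, apply_transform

logger = logging.getLogger(__name__)

N_ANGLES = 360
#: Angle samples (degrees) of the posterior half-plane (+y).
POSTERIOR_ANGLES = np.arange(1, 181)
_POSTERIOR_MASK = np.zeros(N_ANGLES, dtype=bool)
_POSTERIOR_MASK[POSTERIOR_ANGLES] = True


def slice_centroid(polygon) -> tuple[float, float]:
    """Area centroid (y_mm, x_mm) of a closed planar polygon."""
    return polygon_centroid(polygon)


@dataclass
class RadialProfile:
    """Boundary radius of one contour sampled at 1-degree increments."""

    origin: tuple[float, float]  # (y_mm, x_mm)
    radii: np.ndarray            # (360,) mm, NaN where the ray misses
    n_multi_crossing: int = 0    # rays crossing the boundary more than twice

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(N_ANGLES)


def radial_profile(polygon, origin, n_angles: int = N_ANGLES,
                   require_inside: bool = True) -> RadialProfile:
    """Cast rays from ``origin`` at 1-degree increments and return, per angle,
    the distance to the farthest boundary intersection (robust to minor
    non-star-shapedness).

    ``origin`` is (y_mm, x_mm).  With ``require_inside`` the origin must lie
    strictly inside the polygon (guaranteeing an intersection on every ray);
    profiles of a displaced outline about the reference origin may disable the
    check, in which case missing rays yield NaN.
    """
    poly = _as_open_polygon(polygon)
    oy, ox = float(origin[0]), float(origin[1])
    if require_inside and not points_in_polygon([[ox, oy]], poly)[0]:
        raise DegenerateInputError("polar origin lies outside the polygon")

    theta = np.deg2rad(np.arange(n_angles))
    d = np.column_stack([np.cos(theta), np.sin(theta)])      # (A, 2)
    p = poly
    q = np.roll(poly, -1, axis=0)
    e = q - p                                                # (S, 2)
    w = p - (ox, oy)                                         # (S, 2)
    # solve origin + s*d = p + t*e  per (angle, segment)
    denom = d[:, 0][:, None] * e[:, 1][None, :] - d[:, 1][:, None] * e[:, 0][None, :]
    cross_wd = w[:, 0][None, :] * d[:, 1][:, None] - w[:, 1][None, :] * d[:, 0][:, None]
    cross_we = w[:, 0][None, :] * e[:, 1][None, :] - w[:, 1][None, :] * e[:, 0][None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_wd / denom
        s = cross_we / denom
    # tolerant endpoint window: a ray through a shared vertex must hit at
    # least one of the two adjacent segments despite rounding; duplicate hits
    # are harmless because only the farthest intersection is kept
    valid = (np.abs(denom) > 1e-300) & (t >= -1e-9) & (t <= 1.0 + 1e-9) & (s > 1e-12)
    s = np.where(valid, s, np.nan)
    radii = np.full(n_angles, np.nan)
    any_hit = valid.any(axis=1)
    radii[any_hit] = np.nanmax(s[any_hit], axis=1)
    # distinct crossing distances per ray (vertex duplicates merged)
    s_sorted = np.sort(np.where(valid, s, np.inf), axis=1)
    finite = np.isfinite(s_sorted)
    with np.errstate(invalid="ignore"):
        gaps = np.diff(s_sorted, axis=1) > 1e-9
    new_val = finite & np.concatenate([finite[:, :1], gaps], axis=1)
    n_multi = int(np.count_nonzero(new_val.sum(axis=1) > 2))
    if n_multi:
        logger.debug("%d rays crossed the boundary more than twice", n_multi)
    return RadialProfile((oy, ox), radii, n_multi)


def slice_residuals(ref_profile: RadialProfile,
                    adc_profile: RadialProfile) -> np.ndarray:
    """Signed per-angle residual dr(theta) = r_ADC(theta) - r_ref(theta), mm.

    Both profiles must share the same polar origin (the reference centroid).
    """
    if not np.allclose(ref_profile.origin, adc_profile.origin, atol=1e-9):
        raise ContractError("profiles must share the same polar origin")
    return adc_profile.radii - ref_profile.radii


@dataclass
class DistortionResult:
    """Radial residuals and their RMS reductions for one patient/position."""

    residuals: dict[int, np.ndarray]   # slice index -> (360,) signed mm
    rms_whole: float
    rms_posterior: float
    n_slices_used: int
    n_slices_dropped: int = 0
    n_multi_crossing_rays: int = 0
    pooling: str = "pooled"

    def to_dict(self) -> dict:
        return {
            "rms_whole_mm": self.rms_whole,
            "rms_posterior_mm": self.rms_posterior,
            "n_slices_used": self.n_slices_used,
            "n_slices_dropped": self.n_slices_dropped,
            "n_multi_crossing_rays": self.n_multi_crossing_rays,
            "pooling": self.pooling,
            "per_slice_rms_mm": {
                int(k): float(np.sqrt(np.nanmean(r ** 2)))
                for k, r in self.residuals.items()
            },
        }


def _rms(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    return float(np.sqrt(np.mean(values ** 2)))


def rms_reduce(residuals_by_slice: dict[int, np.ndarray],
               n_slices_dropped: int = 0,
               n_multi_crossing_rays: int = 0,
               pooling: str = "pooled") -> DistortionResult:
    """Reduce per-(slice, angle) residuals to whole-gland and posterior RMS.

    ``pooling='pooled'`` (default) pools every (slice, angle) sample with
    equal weight; ``pooling='per_slice'`` first forms per-slice mean squares
    and averages those, weighting slices equally.
    """
    if pooling not in ("pooled", "per_slice"):
        raise ValueError(f"unknown pooling {pooling!r}")
    if not residuals_by_slice:
        raise EmptyPairingError("no paired slices to reduce")
    res = {int(k): np.asarray(v, dtype=float) for k, v in residuals_by_slice.items()}
    if pooling == "pooled":
        all_sq = np.concatenate([r for r in res.values()])
        post_sq = np.concatenate([r[_POSTERIOR_MASK] for r in res.values()])
        rms_whole, rms_post = _rms(all_sq), _rms(post_sq)
    else:
        def per_slice(mask=None):
            means = []
            for r in res.values():
                vals = r if mask is None else r[mask]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    means.append(np.mean(vals ** 2))
            return float(np.sqrt(np.mean(means))) if means else float("nan")
        rms_whole = per_slice()
        rms_post = per_slice(_POSTERIOR_MASK)
    return DistortionResult(res, rms_whole, rms_post, len(res),
                            n_slices_dropped, n_multi_crossing_rays, pooling)


def measure_distortion(ref_contours: ContourSet, adc_contours: ContourSet,
                       transform: MaskTransform | None = None,
                       pooling: str = "pooled") -> DistortionResult:
    """Full distortion measurement between a reference and an ADC contour set.

    Applies the registration transform to the ADC contours, pairs slices by
    index, uses the reference centroid of each slice as the shared polar
    origin, and reduces the signed residuals to RMS values.  Slices present in
    only one acquisition are dropped and counted.
    """
    if transform is not None:
        adc_contours = apply_transform(adc_contours, transform)
    ref_slices = dict(ref_contours.slices)
    adc_slices = dict(adc_contours.slices)
    shared = sorted(set(ref_slices) & set(adc_slices))
    dropped = len(set(ref_slices) ^ set(adc_slices))
    if not shared:
        raise EmptyPairingError("reference and ADC contour sets share no slices")
    residuals: dict[int, np.ndarray] = {}
    n_multi = 0
    for k in shared:
        origin = polygon_centroid(ref_slices[k])
        ref_prof = radial_profile(ref_slices[k], origin)
        adc_prof = radial_profile(adc_slices[k], origin, require_inside=False)
        residuals[k] = slice_residuals(ref_prof, adc_prof)
        n_multi += ref_prof.n_multi_crossing + adc_prof.n_multi_crossing
    return rms_reduce(residuals, dropped, n_multi, pooling)


__all__ = [
    "N_ANGLES",
    "POSTERIOR_ANGLES",
    "RadialProfile",
    "DistortionResult",
    "slice_centroid",
    "radial_profile",
    "slice_residuals",
    "rms_reduce",
    "measure_distortion",
]
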