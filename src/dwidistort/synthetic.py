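"""Synthetic paired supine/prone phantoms and cohorts.

The generator emulates the structure the analysis assumes: an ellipsoidal
prostate with a rectum posterior to it, an air pocket inside the rectum whose
volume is controllable and whose location follows gravity (anterior/near the
prostate when supine, posterior when prone), an ADC outline deformed
posteriorly by an amount that grows with adjacent air volume above a ~4 cm3
knee, 5-point Likert air scores logistically linked to air volume, and
two-rater scores with controllable disagreement.

Deformations are applied to contours in continuous mm space, so the expected
distortion of a deformation spec has a computable ground truth
(:func:`expected_distortion`) that is independent of the ray-casting metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .contours import ContourSet, contours_from_mask, polygon_centroid
from .errors import DwidistortError
from .volumes import AIR, IntensityVolume, LabelVolume, PROSTATE, RECTUM


class SpecError(DwidistortError, ValueError):
    """A phantom/cohort specification is unachievable."""


# ---------------------------------------------------------------------------
# contour-level geometry
# ---------------------------------------------------------------------------

def ellipsoid_contours(semi_axis_x_mm: float = 20.0, semi_axis_y_mm: float = 16.0,
                       semi_axis_z_mm: float = 18.0,
                       center_mm: tuple[float, float, float] = (30.0, 40.0, 48.0),
                       slice_thickness_mm: float = 3.0,
                       n_vertices: int = 360,
                       position: str = "supine",
                       organ: str = "prostate") -> ContourSet:
    """Analytic stack of elliptical slice contours of an ellipsoid organ.

    ``center_mm`` is (z, y, x).  Slices are cut at voxel-center planes
    ``k * slice_thickness_mm``; slices whose in-plane radius would collapse
    below 2 mm are omitted (tip slices carry no stable contour).
    """
    cz, cy, cx = center_mm
    phi = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    slices = []
    k_lo = int(np.ceil((cz - semi_axis_z_mm) / slice_thickness_mm))
    k_hi = int(np.floor((cz + semi_axis_z_mm) / slice_thickness_mm))
    for k in range(max(k_lo, 0), k_hi + 1):
        z = k * slice_thickness_mm
        rel = (z - cz) / semi_axis_z_mm
        if abs(rel) >= 1.0:
            continue
        scale = np.sqrt(1.0 - rel ** 2)
        ax, ay = semi_axis_x_mm * scale, semi_axis_y_mm * scale
        if min(ax, ay) < 2.0:
            continue
        poly = np.column_stack([cx + ax * np.cos(phi), cy + ay * np.sin(phi)])
        slices.append((k, poly))
    return ContourSet(organ, position, slices, slice_thickness_mm=slice_thickness_mm)


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

@dataclass
class DeformationSpec:
    """Posterior susceptibility-like deformation of a contour stack.

    ``posterior_bump`` displaces each vertex along +y (posterior) by
    ``amplitude_mm * exp(-(theta - center_deg)^2 / (2 sigma_deg^2))`` where
    theta is the vertex's polar angle about the slice centroid, tapered
    across slices by a Gaussian of width ``slice_sigma`` (in slices) about
    the mid-slice.  ``radial_dilation`` moves every vertex radially outward
    by ``dilation_mm``.
    """

    amplitude_mm: float = 0.0
    sigma_deg: float = 30.0
    center_deg: float = 90.0
    slice_sigma: float | None = None
    mode: str = "posterior_bump"
    dilation_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0:
            raise ValueError("amplitude must be >= 0")
        if self.mode not in ("posterior_bump", "radial_dilation"):
            raise ValueError(f"unknown deformation mode {self.mode!r}")


def _slice_weights(indices: list[int], spec: DeformationSpec) -> dict[int, float]:
    ks = np.asarray(indices, dtype=float)
    mid = 0.5 * (ks.min() + ks.max())
    sigma = spec.slice_sigma if spec.slice_sigma is not None else max(
        (ks.max() - ks.min()) / 4.0, 0.5)
    w = np.exp(-((ks - mid) ** 2) / (2.0 * sigma ** 2))
    return dict(zip(indices, w))


def _bump_displacement(poly: np.ndarray, origin_yx, w: float,
                       spec: DeformationSpec) -> np.ndarray:
    oy, ox = origin_yx
    theta = np.degrees(np.arctan2(poly[:, 1] - oy, poly[:, 0] - ox)) % 360.0
    dtheta = np.abs((theta - spec.center_deg + 180.0) % 360.0 - 180.0)
    return w * spec.amplitude_mm * np.exp(-dtheta ** 2 / (2.0 * spec.sigma_deg ** 2))


def distort_contours(reference: ContourSet, spec: DeformationSpec) -> ContourSet:
    """Apply a deformation spec to a reference contour set (ADC emulation)."""
    weights = _slice_weights(reference.slice_indices, spec) if reference.slices else {}
    slices = []
    for k, poly in reference.slices:
        origin = polygon_centroid(poly)
        new = poly.copy()
        if spec.mode == "radial_dilation":
            oy, ox = origin
            vec = new - (ox, oy)
            r = np.hypot(vec[:, 0], vec[:, 1])
            new = new + spec.dilation_mm * vec / r[:, None]
        elif spec.amplitude_mm > 0:
            disp = _bump_displacement(poly, origin, weights[k], spec)
            new[:, 1] = new[:, 1] + disp
        slices.append((k, new))
    return ContourSet(reference.organ, reference.position, slices,
                      slice_thickness_mm=reference.slice_thickness_mm)


def expected_distortion(reference: ContourSet, spec: DeformationSpec,
                        n_dense: int = 8192) -> tuple[float, float]:
    """Numerically predicted (rms_whole, rms_posterior) for a deformation.

    Independent of the ray-casting metric: each slice boundary is resampled
    densely by arc length, deformed by the same rule, converted to polar
    coordinates about the *reference* centroid, and the radius difference is
    interpolated onto the 1-degree grid and pooled across slices.
    """
    if spec.mode == "radial_dilation":
        return abs(spec.dilation_mm), abs(spec.dilation_mm)
    weights = _slice_weights(reference.slice_indices, spec) if reference.slices else {}
    grid = np.arange(360.0)
    sq_whole, sq_post = [], []
    for k, poly in reference.slices:
        origin = polygon_centroid(poly)
        oy, ox = origin
        closed = np.vstack([poly, poly[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        u = np.linspace(0.0, arc[-1], n_dense, endpoint=False)
        dense = np.column_stack([np.interp(u, arc, closed[:, 0]),
                                 np.interp(u, arc, closed[:, 1])])
        disp = _bump_displacement(dense, origin, weights[k], spec)
        deformed = dense.copy()
        deformed[:, 1] += disp

        def polar_radius(points):
            vec = points - (ox, oy)
            th = np.degrees(np.arctan2(vec[:, 1], vec[:, 0])) % 360.0
            r = np.hypot(vec[:, 0], vec[:, 1])
            order = np.argsort(th)
            th, r = th[order], r[order]
            th_ext = np.concatenate([th[-1:] - 360.0, th, th[:1] + 360.0])
            r_ext = np.concatenate([r[-1:], r, r[:1]])
            return np.interp(grid, th_ext, r_ext)

        dr = polar_radius(deformed) - polar_radius(dense)
        sq_whole.append(dr ** 2)
        sq_post.append(dr[1:181] ** 2)
    return (float(np.sqrt(np.mean(np.concatenate(sq_whole)))),
            float(np.sqrt(np.mean(np.concatenate(sq_post)))))


# ---------------------------------------------------------------------------
# voxel phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry of one paired-position pelvic phantom."""

    shape: tuple[int, int, int] = (20, 96, 96)
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)
    prostate_center_mm: tuple[float, float, float] = (30.0, 40.0, 48.0)
    prostate_semiaxes_mm: tuple[float, float, float] = (18.0, 16.0, 20.0)  # (z, y, x)
    surface_amplitude: float = 0.04   # relative low-order surface perturbation
    rectum_center_y_mm: float = 68.0
    rectum_semiaxes_mm: tuple[float, float] = (10.0, 14.0)  # (y, x)
    air_volume_cm3: float = 2.0
    position: str = "supine"
    tissue_intensity: float = 100.0
    air_intensity: float = 5.0
    noise_sd: float = 3.0
    seed: int = 0


@dataclass
class Phantom:
    prostate: LabelVolume
    rectum: LabelVolume
    intensity: IntensityVolume
    contours: ContourSet
    air_true: LabelVolume
    spec: PhantomSpec


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one phantom: prostate + rectum masks, intensity volume with a
    dark air pocket of the requested volume, and reference prostate contours.

    The air pocket fills the rectum voxels nearest the prostate when supine
    (gas rises to the rectoprostatic interface) and the farthest when prone.
    The same seed yields bitwise-identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    nk, nj, ni = spec.shape
    dz, dy, dx = spec.spacing
    kk, jj, ii = np.meshgrid(np.arange(nk) * dz, np.arange(nj) * dy,
                             np.arange(ni) * dx, indexing="ij")
    cz, cy, cx = spec.prostate_center_mm
    az, ay, ax = spec.prostate_semiaxes_mm
    # low-order angular perturbation keeps the surface smooth but non-ellipsoidal
    phase = rng.uniform(0.0, 2.0 * np.pi)
    phi = np.arctan2(jj - cy, ii - cx)
    bump = 1.0 + spec.surface_amplitude * np.cos(2.0 * phi + phase)
    prostate = (((ii - cx) / (ax * bump)) ** 2 + ((jj - cy) / (ay * bump)) ** 2
                + ((kk - cz) / az) ** 2) <= 1.0

    ry, rx = spec.rectum_semiaxes_mm
    k_extent = np.abs(kk - cz) <= az  # rectum outlined on the prostate slices
    rectum = ((((ii - cx) / rx) ** 2 + ((jj - spec.rectum_center_y_mm) / ry) ** 2)
              <= 1.0) & k_extent & ~prostate

    vox_cm3 = dz * dy * dx / 1000.0
    n_air = int(round(spec.air_volume_cm3 / vox_cm3))
    if n_air > rectum.sum():
        raise SpecError(
            f"air volume {spec.air_volume_cm3} cm3 exceeds rectum capacity "
            f"({rectum.sum() * vox_cm3:.2f} cm3)")
    air = np.zeros_like(rectum)
    if n_air > 0:
        dist = ndimage.distance_transform_edt(~prostate, sampling=spec.spacing)
        rect_idx = np.argwhere(rectum)
        d = dist[rectum]
        order = np.argsort(d, kind="stable")
        if spec.position == "prone":
            order = order[::-1]
        chosen = rect_idx[order[:n_air]]
        air[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True

    intensity = spec.tissue_intensity + rng.normal(0.0, spec.noise_sd, spec.shape)
    intensity[air] = np.maximum(
        spec.air_intensity + rng.normal(0.0, 1.0, int(air.sum())), 0.0)

    prost_vol = LabelVolume(np.where(prostate, PROSTATE, 0).astype(np.int16),
                            spec.spacing)
    rect_vol = LabelVolume(np.where(rectum, RECTUM, 0).astype(np.int16),
                           spec.spacing)
    air_vol = LabelVolume(np.where(air, AIR, 0).astype(np.int16), spec.spacing)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        contours = contours_from_mask(prost_vol, "prostate", spec.position)
    return Phantom(prost_vol, rect_vol,
                   IntensityVolume(intensity, spec.spacing), contours,
                   air_vol, spec)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Statistical structure of a paired supine/prone cohort.

    Defaults are calibrated so that the generated cohort reproduces the
    study conditions: supine proximal air ~ log-normal with median ~2 cm3 and
    ~37% of patients above 4 cm3; prone air = supine air times a Beta-
    distributed reduction factor; posterior distortion = shared patient
    baseline (median 3 mm) plus ``slope_mm_per_cm3`` per cm3 of air above the
    ``knee_cm3``, with the prone baseline inflated by ``prone_baseline_factor``
    (prone acquisitions trade rectal air for motion-related degradation);
    Likert scores arise from air volume plus logistic noise with the score-4
    cutpoint at the knee, so the appreciable-air judgement is exactly a
    logistic function of air volume.
    """

    n_patients: int = 52
    air_lognorm_mu: float = float(np.log(1.96))
    air_lognorm_sigma: float = 1.4
    air_max_cm3: float = 20.0
    prone_reduction_beta: tuple[float, float] = (1.5, 3.5)
    baseline_mm: float = 3.0
    baseline_sigma: float = 0.40         # log-scale sd of the patient baseline
    slope_mm_per_cm3: float = 0.4
    knee_cm3: float = 4.0
    prone_baseline_factor: float = 1.08
    position_noise_mm: float = 0.5       # per-acquisition additive noise
    likert_noise_scale: float = 1.5      # logistic noise on the latent air score
    likert_cutpoints: tuple[float, ...] = (0.5, 1.5, 4.0, 8.0)
    rater_disagree_prob: float = 0.40    # chance the second rater moves +/-1
    seed: int = 0


@dataclass
class Cohort:
    table: pd.DataFrame
    scores: pd.DataFrame
    spec: CohortSpec
    phantom_specs: list[tuple[PhantomSpec, PhantomSpec]] = field(default_factory=list)


def _likert_from_air(air: np.ndarray, rng: np.random.Generator,
                     spec: CohortSpec) -> np.ndarray:
    latent = air + rng.logistic(0.0, spec.likert_noise_scale, air.shape)
    return 1 + np.sum(latent[:, None] > np.asarray(spec.likert_cutpoints)[None, :],
                      axis=1)


def make_cohort(spec: CohortSpec, with_phantom_specs: bool = False) -> Cohort:
    """Generate a cohort table, two-rater air scores and (optionally) phantom
    specs whose air volumes match the drawn cohort values."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    air_s = np.minimum(rng.lognormal(spec.air_lognorm_mu, spec.air_lognorm_sigma, n),
                       spec.air_max_cm3)
    a, b = spec.prone_reduction_beta
    air_p = air_s * rng.beta(a, b, n)
    base = np.exp(rng.normal(np.log(spec.baseline_mm), spec.baseline_sigma, n))

    def response(air):
        return spec.slope_mm_per_cm3 * np.maximum(0.0, air - spec.knee_cm3)

    noise = rng.normal(0.0, spec.position_noise_mm, (2, n))
    dist_s = np.maximum(base + response(air_s) + noise[0], 0.2)
    dist_p = np.maximum(base * spec.prone_baseline_factor + response(air_p)
                        + noise[1], 0.2)
    lik_s = _likert_from_air(air_s, rng, spec)
    lik_p = _likert_from_air(air_p, rng, spec)

    table = pd.DataFrame({
        "patient_id": [f"P{i + 1:03d}" for i in range(n)],
        "air_supine_cm3": air_s,
        "air_prone_cm3": air_p,
        "distortion_supine_mm": dist_s,
        "distortion_prone_mm": dist_p,
        "likert_supine": lik_s,
        "likert_prone": lik_p,
    })

    rows = []
    for pos, lik in (("supine", lik_s), ("prone", lik_p)):
        move = rng.random(n) < spec.rater_disagree_prob
        step = rng.choice([-1, 1], n)
        r2 = np.clip(lik + np.where(move, step, 0), 1, 5)
        for i in range(n):
            rows.append((f"P{i + 1:03d}", "R1", f"rectal_air_{pos}", int(lik[i])))
            rows.append((f"P{i + 1:03d}", "R2", f"rectal_air_{pos}", int(r2[i])))
    scores = pd.DataFrame(rows, columns=["subject", "rater", "item", "score"])

    phantom_specs: list[tuple[PhantomSpec, PhantomSpec]] = []
    if with_phantom_specs:
        base_spec = PhantomSpec()
        for i in range(n):
            seed_i = int((spec.seed * 100003 + i) % (2 ** 31 - 1))
            phantom_specs.append((
                replace(base_spec, air_volume_cm3=float(min(air_s[i], 12.0)),
                        position="supine", seed=seed_i),
                replace(base_spec, air_volume_cm3=float(min(air_p[i], 12.0)),
                        position="prone", seed=seed_i),
            ))
    return Cohort(table, scores, spec, phantom_specs)


__all__ = [
    "SpecError",
    "ellipsoid_contours",
    "DeformationSpec",
    "distort_contours",
    "expected_distortion",
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "CohortSpec",
    "Cohort",
    "make_cohort",
]
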