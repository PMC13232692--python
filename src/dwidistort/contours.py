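"""Per-slice closed planar contours and their conversion to/from voxel masks.

Contours live in physical mm within each axial slice plane: ``x`` increases
patient-right -> patient-left (column direction), ``y`` increases anterior ->
posterior (row direction).  Voxel centers sit at ``(i * dx, j * dy)``; voxel
indices are 0-based.  Polygons are stored open (the closing edge from the last
vertex back to the first is implicit).

Rasterization uses the even-odd crossing rule evaluated at voxel centers with
the conventional half-open boundary treatment (a center exactly on the lower/
left boundary is inside, on the upper/right boundary outside), which makes an
axis-aligned W x H mm rectangle on 1 mm voxels cover exactly W*H voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .errors import BoundsError, DegenerateInputError, SchemaError
from .volumes import LABELS, LabelVolume

POSITIONS = ("supine", "prone")

CONTOUR_COLUMNS = ["position", "organ", "slice_index", "vertex_order", "x_mm", "y_mm"]


# ---------------------------------------------------------------------------
# polygon primitives
# ---------------------------------------------------------------------------

def _as_open_polygon(vertices) -> np.ndarray:
    poly = np.asarray(vertices, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2:
        raise ValueError("polygon must be an (N, 2) array of (x_mm, y_mm)")
    if len(poly) >= 2 and np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    if len(poly) < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    return poly


def polygon_area(polygon) -> float:
    """Signed shoelace area in mm^2 (positive for counter-clockwise in (x, y))."""
    p = _as_open_polygon(polygon)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(polygon) -> tuple[float, float]:
    """Area centroid (y_mm, x_mm) of the polygon interior."""
    p = _as_open_polygon(polygon)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        raise DegenerateInputError("zero-area polygon has no centroid")
    cx = float(np.sum((x + xn) * cross) / (6.0 * a))
    cy = float(np.sum((y + yn) * cross) / (6.0 * a))
    return (cy, cx)


def points_in_polygon(points, polygon) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorized.

    Half-open boundary rule: edges on the increasing-x / increasing-y side of
    the interior are excluded, so adjacent polygons tile the plane without
    double-counting voxel centers.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = _as_open_polygon(polygon)
    x = pts[:, 0][:, None]
    y = pts[:, 1][:, None]
    x0, y0 = poly[:, 0][None, :], poly[:, 1][None, :]
    x1, y1 = np.roll(poly[:, 0], -1)[None, :], np.roll(poly[:, 1], -1)[None, :]
    crosses = (y0 > y) != (y1 > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = x0 + (y - y0) / (y1 - y0) * (x1 - x0)
    hits = crosses & (x < xi)
    return np.bitwise_xor.reduce(hits, axis=1)


# ---------------------------------------------------------------------------
# ContourSet
# ---------------------------------------------------------------------------

@dataclass
class ContourSet:
    """Closed contours of one organ across axial slices of one acquisition.

    ``slices`` maps each integer slice index to an open (N, 2) vertex array of
    (x_mm, y_mm) coordinates; slice indices are strictly increasing.
    """

    organ: str
    position: str
    slices: list[tuple[int, np.ndarray]] = field(default_factory=list)
    slice_thickness_mm: float | None = None

    def __post_init__(self) -> None:
        if self.organ not in LABELS or self.organ == "background":
            raise ValueError(f"unknown organ {self.organ!r}")
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}, got {self.position!r}")
        cleaned: list[tuple[int, np.ndarray]] = []
        last = None
        for k, poly in self.slices:
            k = int(k)
            if last is not None and k <= last:
                raise ValueError("slice indices must be strictly increasing")
            last = k
            cleaned.append((k, _as_open_polygon(poly)))
        self.slices = cleaned

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def slice_indices(self) -> list[int]:
        return [k for k, _ in self.slices]

    def polygon(self, slice_index: int) -> np.ndarray:
        for k, poly in self.slices:
            if k == slice_index:
                return poly
        raise KeyError(slice_index)

    @property
    def label(self) -> int:
        return LABELS[self.organ]


# ---------------------------------------------------------------------------
# mask <-> contour conversion
# ---------------------------------------------------------------------------

def mask_from_contours(contours: ContourSet, template: LabelVolume) -> LabelVolume:
    """Rasterize a contour set onto the template grid (paper pipeline step 1).

    A voxel is set iff its in-plane center lies inside the slice polygon under
    the even-odd rule; slices without contours stay empty.
    """
    nk, nj, ni = template.shape
    dz, dy, dx = template.spacing
    out = np.zeros(template.shape, dtype=np.int16)
    xs = np.arange(ni) * dx
    ys = np.arange(nj) * dy
    gx, gy = np.meshgrid(xs, ys)  # (nj, ni)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    for k, poly in contours.slices:
        if not (0 <= k < nk):
            raise BoundsError(f"contour slice index {k} outside grid with {nk} slices")
        if (poly[:, 0].min() < -0.5 * dx or poly[:, 0].max() > (ni - 0.5) * dx
                or poly[:, 1].min() < -0.5 * dy or poly[:, 1].max() > (nj - 0.5) * dy):
            raise BoundsError(f"contour on slice {k} extends outside the grid")
        inside = points_in_polygon(centers, poly).reshape(nj, ni)
        out[k][inside] = contours.label
    return LabelVolume(out, template.spacing)


def contours_from_mask(mask: LabelVolume, organ: str,
                       position: str = "supine") -> ContourSet:
    """Extract one outer closed polygon per slice from a label mask.

    Uses subpixel marching squares at the 0.5 level of the binary organ mask.
    When a slice fragments into several components, the largest-area outline
    is kept and a warning is emitted.
    """
    label = LABELS[organ]
    dz, dy, dx = mask.spacing
    slices: list[tuple[int, np.ndarray]] = []
    for k in range(mask.shape[0]):
        binary = (mask.voxels[k] == label).astype(float)
        if not binary.any():
            continue
        padded = np.pad(binary, 1)
        rings = measure.find_contours(padded, 0.5)
        polys = []
        for ring in rings:
            rc = ring - 1.0  # undo padding
            poly = np.column_stack([rc[:, 1] * dx, rc[:, 0] * dy])
            try:
                poly = _as_open_polygon(poly)
            except ValueError:
                continue
            polys.append((abs(polygon_area(poly)), poly))
        if not polys:
            continue
        if len(polys) > 1:
            warnings.warn(
                f"slice {k}: {len(polys)} {organ} components, keeping largest",
                RuntimeWarning, stacklevel=2)
        _, best = max(polys, key=lambda t: t[0])
        if polygon_area(best) < 0:
            best = best[::-1]
        slices.append((k, best))
    return ContourSet(organ, position, slices, slice_thickness_mm=dz)


def grid_for_contours(contour_sets, spacing=(3.0, 1.0, 1.0),
                      margin_mm: float = 5.0) -> LabelVolume:
    """Empty template grid covering the given contour sets with a margin."""
    dz, dy, dx = spacing
    max_k, max_x, max_y = 0, 0.0, 0.0
    for cs in contour_sets:
        for k, poly in cs.slices:
            max_k = max(max_k, k)
            max_x = max(max_x, poly[:, 0].max())
            max_y = max(max_y, poly[:, 1].max())
    shape = (max_k + 1,
             int(np.ceil((max_y + margin_mm) / dy)) + 1,
             int(np.ceil((max_x + margin_mm) / dx)) + 1)
    return LabelVolume(np.zeros(shape, dtype=np.int16), spacing)


# ---------------------------------------------------------------------------
# contour CSV I/O
# ---------------------------------------------------------------------------

def write_contours(contour_sets, path) -> None:
    """Write one or more contour sets to the documented CSV schema."""
    if isinstance(contour_sets, ContourSet):
        contour_sets = [contour_sets]
    rows = []
    for cs in contour_sets:
        for k, poly in cs.slices:
            for order, (x, y) in enumerate(poly):
                rows.append((cs.position, cs.organ, k, order, x, y))
    pd.DataFrame(rows, columns=CONTOUR_COLUMNS).to_csv(path, index=False)


def read_contours(path, slice_thickness_mm: float | None = None) -> list[ContourSet]:
    """Read contour sets from CSV (columns: position, organ, slice_index,
    vertex_order, x_mm, y_mm); unknown columns are rejected."""
    df = pd.read_csv(path)
    extra = set(df.columns) - set(CONTOUR_COLUMNS)
    if extra:
        raise SchemaError(f"unknown contour columns {sorted(extra)}")
    missing = set(CONTOUR_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing contour columns {sorted(missing)}")
    out = []
    for (position, organ), grp in df.groupby(["position", "organ"], sort=True):
        slices = []
        for k, sgrp in grp.groupby("slice_index", sort=True):
            sgrp = sgrp.sort_values("vertex_order")
            slices.append((int(k), sgrp[["x_mm", "y_mm"]].to_numpy(float)))
        out.append(ContourSet(str(organ), str(position), slices,
                              slice_thickness_mm=slice_thickness_mm))
    return out


def get_contour_set(contour_sets, position: str, organ: str) -> ContourSet:
    for cs in contour_sets:
        if cs.position == position and cs.organ == organ:
            return cs
    raise KeyError((position, organ))


__all__ = [
    "POSITIONS",
    "CONTOUR_COLUMNS",
    "ContourSet",
    "polygon_area",
    "polygon_centroid",
    "points_in_polygon",
    "mask_from_contours",
    "contours_from_mask",
    "grid_for_contours",
    "read_contours",
    "write_contours",
    "get_contour_set",
]
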