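"""Geometric complexity: Convexity C, Packing P, box-counting dimension D.

The three metrics compare a reef model with its convex hull and with its
own behaviour across spatial scales:

* ``C = (V_hull - V_mesh) / V_hull`` — the fraction of the hull volume that
  is accessible to mobile organisms.  0 for a filled convex solid, tending
  to 1 for an empty frame.
* ``P = A_hull / A_mesh`` — hull-to-model surface ratio; low values mean a
  highly folded surface.  P <= 1 for watertight meshes (the convex hull is
  the area-minimizing enclosure); open shells can exceed 1 and are flagged.
* ``D`` — Minkowski-Bouligand (box-counting) dimension of the surface point
  cloud: the OLS slope of log(occupied boxes) versus log(1/box size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import linregress

from .errors import (
    DegenerateInputError,
    InconsistencyError,
    InsufficientScaleRangeError,
    ParameterError,
)
from .mesh_io import PointSample, TriangleMesh

__all__ = [
    "HullSummary",
    "GeometricMetrics",
    "BoxCountTable",
    "convex_hull",
    "convexity",
    "packing",
    "box_count",
    "fractal_dimension",
    "geometric_metrics",
]


@dataclass
class HullSummary:
    hull_mesh: TriangleMesh
    hull_area: float
    hull_volume: float


@dataclass
class GeometricMetrics:
    C: float
    P: float
    D: float
    fit_r2: float
    n_scales: int
    packing_exceeds_one: bool = False
    volume_is_fallback: bool = False


@dataclass
class BoxCountTable:
    """Occupied-box counts over a descending geometric series of box sizes."""

    box_sizes: np.ndarray
    counts: np.ndarray
    grid_origin: np.ndarray

    def __len__(self) -> int:
        return len(self.box_sizes)


def convex_hull(mesh: TriangleMesh) -> HullSummary:
    """Convex hull of the vertex set, with its surface area and volume."""
    try:
        hull = ConvexHull(mesh.vertices)
    except QhullError as exc:
        raise DegenerateInputError(
            f"convex hull of {mesh.name or 'mesh'} is degenerate "
            "(coplanar or collinear vertices)"
        ) from exc
    # re-index the hull triangulation over its own vertex subset
    used = np.unique(hull.simplices)
    remap = np.full(len(mesh.vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    hull_mesh, _, _ = _oriented(mesh.vertices[used], remap[hull.simplices])
    return HullSummary(
        hull_mesh=hull_mesh,
        hull_area=float(hull.area),
        hull_volume=float(hull.volume),
    )


def _oriented(vertices: np.ndarray, faces: np.ndarray):
    from .mesh_io import clean_mesh

    return clean_mesh(vertices, faces, name="hull")


def convexity(mesh_volume: float, hull: HullSummary) -> float:
    """Accessible-volume fraction of the hull: (V_hull - V_mesh) / V_hull."""
    if hull.hull_volume <= 0:
        raise DegenerateInputError("hull volume is not positive")
    if mesh_volume > hull.hull_volume * (1.0 + 1e-6):
        raise InconsistencyError(
            f"mesh volume {mesh_volume} exceeds hull volume {hull.hull_volume}"
        )
    v = min(max(mesh_volume, 0.0), hull.hull_volume)
    return (hull.hull_volume - v) / hull.hull_volume


def packing(mesh_area: float, hull: HullSummary) -> tuple[float, bool]:
    """Hull-to-model surface ratio and a flag for open-shell values > 1."""
    if mesh_area <= 0:
        raise ParameterError("mesh area must be positive")
    p = hull.hull_area / mesh_area
    return p, bool(p > 1.0 + 1e-9)


# ---------------------------------------------------------------------------
# box counting
# ---------------------------------------------------------------------------

#: relative inward nudge applied to points lying exactly on grid planes
_SOLID_SIDE_EPS = 1e-9


def box_count(
    sample: PointSample,
    n_scales: int | None = None,
    size_range=None,
) -> BoxCountTable:
    """Count occupied cells of axis-aligned grids anchored at the bbox corner.

    By default the box sizes form a ratio-2 geometric series from the
    largest bounding-box edge down to twice the mean point spacing.  Pass an
    explicit descending sequence via ``size_range`` to control the fitting
    window (at least 5 sizes).

    Two conventions keep counts faithful for surfaces that lie exactly on
    grid planes (flat-faced CAD models): each point is attributed to the
    cell on its *solid* side (a tiny inward nudge along its normal), and
    indices are clipped to the bounding-box grid so points on the far bbox
    face do not open a spurious extra cell layer.
    """
    pts = np.asarray(sample.points, dtype=np.float64)
    if len(pts) < 100:
        raise ParameterError(f"box counting needs >= 100 points, got {len(pts)}")
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    extent = hi - lo
    max_edge = float(extent.max())
    if max_edge <= 0:
        raise DegenerateInputError("point cloud has zero extent")

    if size_range is not None:
        sizes = np.asarray(sorted(np.atleast_1d(size_range), reverse=True), dtype=float)
        if n_scales is not None:
            sizes = sizes[: int(n_scales)]
    else:
        min_size = 2.0 * sample.mean_spacing()
        if n_scales is not None:
            k = int(n_scales)
        else:
            if min_size <= 0 or min_size >= max_edge:
                raise InsufficientScaleRangeError(
                    "point spacing too coarse relative to the bounding box"
                )
            k = int(np.floor(np.log2(max_edge / min_size))) + 1
        sizes = max_edge / (2.0 ** np.arange(k))
        sizes = sizes[sizes >= min_size * (1.0 - 1e-12)]
    if len(sizes) < 5:
        raise InsufficientScaleRangeError(
            f"only {len(sizes)} usable box sizes (need >= 5); "
            "increase sampling resolution or pass explicit sizes"
        )

    q = pts
    if sample.normals is not None and len(sample.normals) == len(pts):
        q = pts - (_SOLID_SIDE_EPS * max_edge) * np.asarray(sample.normals)

    counts = np.empty(len(sizes), dtype=np.int64)
    for i, s in enumerate(sizes):
        nbins = np.maximum(np.ceil(extent / s - 1e-12).astype(np.int64), 1)
        idx = np.floor((q - lo) / s).astype(np.int64)
        idx = np.clip(idx, 0, nbins - 1)
        counts[i] = len(np.unique(idx, axis=0))
    return BoxCountTable(box_sizes=sizes, counts=counts, grid_origin=lo.copy())


def fractal_dimension(table: BoxCountTable) -> tuple[float, float]:
    """OLS slope of log(count) vs log(1/size), clamped to [0, 3], with R^2."""
    if len(table) < 5:
        raise InsufficientScaleRangeError("need >= 5 scales to fit a dimension")
    x = np.log(1.0 / table.box_sizes)
    y = np.log(table.counts.astype(float))
    if np.ptp(x) <= 0:
        raise ParameterError("zero variance in log box sizes")
    if np.ptp(y) == 0:  # all counts equal (e.g. a single point)
        return (0.0, 1.0)
    fit = linregress(x, y)
    d = float(np.clip(fit.slope, 0.0, 3.0))
    return d, float(fit.rvalue**2)


def geometric_metrics(
    mesh: TriangleMesh,
    sample: PointSample,
    mesh_volume: float | None = None,
    n_scales: int | None = None,
    size_range=None,
) -> GeometricMetrics:
    """Assemble C, P and D for one model.

    ``mesh_volume`` defaults to the divergence-theorem volume and must be
    supplied explicitly (e.g. a voxel-fill estimate) for open meshes.
    """
    hull = convex_hull(mesh)
    fallback = False
    if mesh_volume is None:
        mesh_volume = mesh.enclosed_volume
        if mesh_volume is None:
            from .mesh_io import summarize_mesh

            mesh_volume = summarize_mesh(mesh).voxel_volume
            fallback = True
    c = convexity(mesh_volume, hull)
    p, p_flag = packing(mesh.total_area, hull)
    table = box_count(sample, n_scales=n_scales, size_range=size_range)
    d, r2 = fractal_dimension(table)
    return GeometricMetrics(
        C=c,
        P=p,
        D=d,
        fit_r2=r2,
        n_scales=len(table),
        packing_exceeds_one=p_flag,
        volume_is_fallback=fallback,
    )
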