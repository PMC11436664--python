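"""Informational complexity: orientation richness R, diversity H, evenness J.

Species-diversity indices applied to the distribution of surface normal
vectors.  A flat-faced mould has a handful of orientations among millions of
sampled normals (R near 0); an organic 3D-printed surface has nearly all
normals distinct (R near 1).  H is the Shannon entropy of the orientation
distribution in nats, and J = H / ln S is Pielou's evenness.

Two category systems are supported:

* ``unique-vector`` — normals rounded componentwise (default 2 decimals)
  and counted as distinct categories.  Used for R, whose printed range only
  makes sense when categories are (quantized) unique vectors.
* ``sphere-binned`` — normals assigned to a fixed equal-area partition of
  the unit sphere (subdivided-icosahedron face cells, default 320).  Used
  for H and J so the entropy has a sample-size-independent ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import entropy as _shannon_entropy

from .errors import ParameterError
from .mesh_io import PointSample

__all__ = [
    "OrientationDistribution",
    "InformationalMetrics",
    "quantize_normals",
    "bin_normals_sphere",
    "sphere_cell_centers",
    "orientation_richness",
    "shannon_diversity",
    "evenness",
    "informational_metrics",
]


@dataclass
class OrientationDistribution:
    """A categorical distribution over surface-normal orientations."""

    mode: str  # "unique-vector" | "sphere-binned"
    categories: np.ndarray  # (S, 3) representative unit vectors
    proportions: np.ndarray  # (S,) fractions summing to 1
    n_samples: int
    n_cells: int | None = None  # size of the partition (sphere-binned only)

    @property
    def S(self) -> int:
        """Number of occupied orientation categories."""
        return int(len(self.proportions))


@dataclass
class InformationalMetrics:
    R: float
    H: float
    J: float
    richness_mode: str = "unique-vector"
    diversity_mode: str = "sphere-binned"


def quantize_normals(sample: PointSample, decimals: int = 2) -> OrientationDistribution:
    """Category = normal rounded componentwise to ``decimals`` places.

    The rounded vector (with -0.0 folded into 0.0) is the category key; the
    stored representative is its re-normalization.
    """
    normals = np.asarray(sample.normals, dtype=np.float64)
    if len(normals) < 1:
        raise ParameterError("need at least one normal")
    key = np.round(normals, int(decimals)) + 0.0
    cats, counts = np.unique(key, axis=0, return_counts=True)
    norms = np.linalg.norm(cats, axis=1)
    reps = np.where(norms[:, None] > 0, cats / np.maximum(norms[:, None], 1e-300), cats)
    return OrientationDistribution(
        mode="unique-vector",
        categories=reps,
        proportions=counts / counts.sum(),
        n_samples=len(normals),
    )


@lru_cache(maxsize=8)
def _cell_centers_cached(subdivisions: int) -> np.ndarray:
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    centers = np.asarray(ico.triangles_center)
    return centers / np.linalg.norm(centers, axis=1, keepdims=True)


def sphere_cell_centers(n_cells: int = 320) -> np.ndarray:
    """Centers of an equal-area icosahedral partition with >= n_cells cells.

    Subdividing an icosahedron s times yields 20 * 4**s spherical triangles
    of equal area; the smallest such partition with at least ``n_cells``
    cells is used (320 is exactly subdivision 2).
    """
    if n_cells < 2:
        raise ParameterError("n_cells must be >= 2")
    s = 0
    while 20 * 4**s < n_cells:
        s += 1
    return _cell_centers_cached(s)


def bin_normals_sphere(sample: PointSample, n_cells: int = 320) -> OrientationDistribution:
    """Assign each normal to the nearest cell center of the sphere partition."""
    from scipy.spatial import cKDTree

    normals = np.asarray(sample.normals, dtype=np.float64)
    if len(normals) < 1:
        raise ParameterError("need at least one normal")
    centers = sphere_cell_centers(n_cells)
    # nearest center in Euclidean distance == max dot product for unit vectors
    _, cell = cKDTree(centers).query(normals, k=1)
    occupied, counts = np.unique(cell, return_counts=True)
    return OrientationDistribution(
        mode="sphere-binned",
        categories=centers[occupied],
        proportions=counts / counts.sum(),
        n_samples=len(normals),
        n_cells=len(centers),
    )


def orientation_richness(dist: OrientationDistribution) -> float:
    """R = occupied categories per sampled normal (S / n); dimensionless <= 1."""
    return dist.S / dist.n_samples


def shannon_diversity(dist: OrientationDistribution) -> float:
    """H = -sum p_i ln p_i in nats (0 ln 0 := 0)."""
    return float(_shannon_entropy(dist.proportions))


def evenness(dist: OrientationDistribution, H: float | None = None) -> float:
    """Pielou's J = H / ln S; a single orientation is trivially even (J = 1)."""
    if dist.S <= 1:
        return 1.0
    if H is None:
        H = shannon_diversity(dist)
    return float(H / np.log(dist.S))


def informational_metrics(
    sample: PointSample,
    decimals: int = 2,
    n_cells: int = 320,
    richness_mode: str = "unique-vector",
    diversity_mode: str = "sphere-binned",
) -> InformationalMetrics:
    """R from the unique-vector distribution, H and J from the sphere bins.

    Both modes can be overridden; the modes used are recorded on the result
    for provenance.
    """

    def _dist(mode: str) -> OrientationDistribution:
        if mode == "unique-vector":
            return quantize_normals(sample, decimals=decimals)
        if mode == "sphere-binned":
            return bin_normals_sphere(sample, n_cells=n_cells)
        raise ParameterError(f"unknown orientation mode {mode!r}")

    rich = _dist(richness_mode)
    div = rich if diversity_mode == richness_mode else _dist(diversity_mode)
    h = shannon_diversity(div)
    return InformationalMetrics(
        R=orientation_richness(rich),
        H=h,
        J=evenness(div, h),
        richness_mode=richness_mode,
        diversity_mode=diversity_mode,
    )
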