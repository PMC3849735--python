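"""Region-scale spatial-heterogeneity statistics on nucleus positions.

Two partitions of the tissue are used.  The Voronoï tessellation
assigns each stained nucleus its zone of influence — the polygon of
all locations closer to it than to any other nucleus; where nuclei
crowd together the pavements are small, which is what the hot-spot
detector exploits.  A fixed quadrat grid provides counting units for
Fisher's index of dispersion (variance-to-mean ratio of quadrat
counts, ≈1 under complete spatial randomness, >1 under clustering)
and for the normalized variance of local density (squared coefficient
of variation of count/area, dimensionless and intensity-free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon, box

from .geometry import PointPattern, Region

__all__ = [
    "VoronoiTessellation",
    "QuadratCounts",
    "HotSpot",
    "voronoi_tessellation",
    "voronoi_area_variance",
    "detect_hot_spots",
    "quadrat_counts",
    "fisher_index",
    "normalized_density_variance",
]


@dataclass(frozen=True)
class VoronoiTessellation:
    """ROI-clipped Voronoï cells, one per generating nucleus."""

    points: np.ndarray  # (n, 2) generators
    cells: list  # shapely Polygons (possibly empty if a cell fell outside the ROI)
    areas: np.ndarray  # µm², one per generator
    roi: Polygon
    adjacency: list  # list of (i, j) index pairs sharing a Voronoï ridge

    @property
    def n_cells(self) -> int:
        return int(np.sum(self.areas > 0))

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            {"cell": i, "x_um": p[0], "y_um": p[1], "area_um2": a, "wkt": c.wkt}
            for i, (p, a, c) in enumerate(zip(self.points, self.areas, self.cells))
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def voronoi_tessellation(pattern: PointPattern, region: Region | None = None) -> VoronoiTessellation:
    """Euclidean Voronoï diagram of the pattern, clipped to the ROI.

    Cells are bounded by mirroring the generators across the four sides
    of the ROI bounding box before triangulating, then intersecting
    each cell with the ROI polygon; the cell areas therefore partition
    the ROI exactly (up to floating-point tolerance).

    Requires ≥ 3 non-collinear points.
    """
    region = region or pattern.region
    pts = pattern.points
    if pts.shape[0] < 3:
        raise ValueError("Voronoï tessellation needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise ValueError("points are collinear")
    roi = region.roi_polygon
    minx, miny, maxx, maxy = roi.bounds
    mirrored = np.vstack(
        [
            pts,
            np.column_stack([2 * minx - pts[:, 0], pts[:, 1]]),
            np.column_stack([2 * maxx - pts[:, 0], pts[:, 1]]),
            np.column_stack([pts[:, 0], 2 * miny - pts[:, 1]]),
            np.column_stack([pts[:, 0], 2 * maxy - pts[:, 1]]),
        ]
    )
    vor = Voronoi(mirrored)
    n = pts.shape[0]
    cells, areas = [], np.zeros(n)
    for i in range(n):
        verts = vor.regions[vor.point_region[i]]
        if -1 in verts or len(verts) < 3:
            # cannot happen for interior points after mirroring, but guard anyway
            cell = Polygon()
        else:
            cell = Polygon(vor.vertices[verts]).intersection(roi)
        cells.append(cell)
        areas[i] = cell.area
    adjacency = [
        (int(a), int(b))
        for a, b in vor.ridge_points
        if a < n and b < n and areas[a] > 0 and areas[b] > 0
    ]
    return VoronoiTessellation(pts, cells, areas, roi, adjacency)


def voronoi_area_variance(tess: VoronoiTessellation, normalized: bool = False) -> float:
    """Sample variance of the Voronoï cell areas (µm⁴).

    With ``normalized=True`` the variance is divided by the squared
    mean cell area, giving a dimensionless heterogeneity index that is
    0 for a perfectly regular pavement and grows with clustering.
    """
    areas = tess.areas[tess.areas > 0]
    if areas.size < 2:
        raise ValueError("need at least 2 cells for a variance")
    v = float(np.var(areas, ddof=1))
    if normalized:
        v /= float(np.mean(areas)) ** 2
    return v


@dataclass(frozen=True)
class HotSpot:
    """Contiguous group of small Voronoï pavements."""

    cell_indices: tuple
    polygon: Polygon

    @property
    def n_cells(self) -> int:
        return len(self.cell_indices)


def detect_hot_spots(
    tess: VoronoiTessellation, area_percentile: float = 10.0, min_cluster: int = 5
) -> list:
    """Locally dense clusters of nuclei, via small adjacent Voronoï cells.

    Cells with area strictly below the given percentile of all cell
    areas are flagged; flagged cells sharing a Voronoï ridge are merged
    and groups of at least ``min_cluster`` cells are returned (largest
    first), each with the union polygon of its pavements.
    """
    areas = tess.areas[tess.areas > 0]
    if areas.size == 0:
        return []
    cut = float(np.percentile(areas, area_percentile))
    flagged = np.flatnonzero((tess.areas > 0) & (tess.areas < cut))
    if flagged.size == 0:
        return []
    fset = set(int(i) for i in flagged)
    parent = {i: i for i in fset}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in tess.adjacency:
        if a in fset and b in fset:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups: dict[int, list] = {}
    for i in fset:
        groups.setdefault(find(i), []).append(i)
    spots = []
    for members in groups.values():
        if len(members) >= min_cluster:
            union = shapely.unary_union([tess.cells[i] for i in members])
            spots.append(HotSpot(tuple(sorted(members)), union))
    return sorted(spots, key=lambda s: -s.n_cells)


@dataclass(frozen=True)
class QuadratCounts:
    """Counts of nuclei in an axis-aligned quadrat grid over the ROI.

    Only quadrats whose overlap with the ROI is at least half the
    quadrat area are retained for statistics; densities use the actual
    overlap area of each quadrat.
    """

    side_um: float
    origin: tuple  # (x0, y0) of the grid
    shape: tuple  # (ny, nx)
    counts: np.ndarray  # retained quadrat counts
    overlap_um2: np.ndarray  # retained quadrat ∩ ROI areas
    counts_all: np.ndarray  # (ny, nx) counts of every quadrat
    total_points: int

    @property
    def n_retained(self) -> int:
        return int(self.counts.size)


def quadrat_counts(pattern: PointPattern, quadrat_side_um: float) -> QuadratCounts:
    """Bin the pattern into square quadrats tiling the ROI bounding box.

    Raises if fewer than 4 quadrats survive the ≥50% ROI-overlap filter.
    """
    if not quadrat_side_um > 0:
        raise ValueError("quadrat side must be positive")
    roi = pattern.region.roi_polygon
    minx, miny, maxx, maxy = roi.bounds
    s = float(quadrat_side_um)
    nx = max(int(np.ceil((maxx - minx) / s - 1e-9)), 1)
    ny = max(int(np.ceil((maxy - miny) / s - 1e-9)), 1)
    pts = pattern.points
    if len(pts):
        ix = np.clip(((pts[:, 0] - minx) / s).astype(int), 0, nx - 1)
        iy = np.clip(((pts[:, 1] - miny) / s).astype(int), 0, ny - 1)
        counts_all = np.bincount(iy * nx + ix, minlength=ny * nx).reshape(ny, nx)
    else:
        counts_all = np.zeros((ny, nx), int)
    # overlap areas; fast path when the ROI is exactly its bounding rectangle
    gx = minx + np.arange(nx) * s
    gy = miny + np.arange(ny) * s
    if roi.equals(box(minx, miny, maxx, maxy)):
        wx = np.minimum(gx + s, maxx) - gx
        wy = np.minimum(gy + s, maxy) - gy
        overlap = np.outer(wy, wx)
    else:
        overlap = np.empty((ny, nx))
        for j in range(ny):
            for i in range(nx):
                overlap[j, i] = roi.intersection(box(gx[i], gy[j], gx[i] + s, gy[j] + s)).area
    retained = overlap >= 0.5 * s * s
    if retained.sum() < 4:
        raise ValueError("ROI too small: fewer than 4 quadrats retained")
    return QuadratCounts(
        side_um=s,
        origin=(float(minx), float(miny)),
        shape=(ny, nx),
        counts=counts_all[retained].astype(float),
        overlap_um2=overlap[retained],
        counts_all=counts_all,
        total_points=int(len(pts)),
    )


def fisher_index(counts: QuadratCounts) -> float:
    """Fisher's index of dispersion: variance/mean of quadrat counts.

    Sample (n−1) variance.  ≈1 for complete spatial randomness
    (Poisson counts), →0 for regular patterns, >1 for clustering.
    """
    c = counts.counts
    if c.size < 2:
        raise ValueError("need at least 2 retained quadrats")
    m = float(c.mean())
    if m <= 0:
        raise ValueError("mean quadrat count is zero")
    return float(np.var(c, ddof=1)) / m


def normalized_density_variance(counts: QuadratCounts) -> float:
    """Squared coefficient of variation of local density.

    Density of each retained quadrat is count / (quadrat ∩ ROI area);
    the statistic is sample variance / squared mean of those
    densities — dimensionless and invariant to global intensity
    rescaling.
    """
    if counts.counts.size < 2:
        raise ValueError("need at least 2 retained quadrats")
    dens = counts.counts / counts.overlap_um2
    m = float(dens.mean())
    if m <= 0:
        raise ValueError("mean density is zero")
    return float(np.var(dens, ddof=1)) / m**2


def nearest_generator_index(tess: VoronoiTessellation, probes: np.ndarray) -> np.ndarray:
    """Index of the nearest generator for each probe point (diagnostic)."""
    tree = cKDTree(tess.points)
    return tree.query(np.asarray(probes, float))[1]
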