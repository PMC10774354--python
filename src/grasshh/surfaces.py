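"""Rasterized surface models from photogrammetric point clouds.

Implements the DSM / DTM / CHM chain used for grassland canopy analysis:
the digital surface model is a Delaunay-TIN rasterization of per-cell
highest points, the digital terrain model is the same rasterization after
keeping only the lowest point in every 0.5 m filter cell, and the canopy
height model is their cell-wise difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

__all__ = [
    "PointCloud",
    "RasterGrid",
    "DegenerateGeometryError",
    "GridGeometryError",
    "filter_lowest_points",
    "tin_interpolate",
    "build_dsm",
    "build_dtm",
    "build_chm",
    "grid_for_bounds",
]


class DegenerateGeometryError(ValueError):
    """Raised when a point set cannot be triangulated (< 3 points or collinear)."""


class GridGeometryError(ValueError):
    """Raised when two rasters that must share a grid do not."""


@dataclass(frozen=True)
class PointCloud:
    """A set of 3D points in a planar projected coordinate system (meters).

    ``xyz`` is an (N, 3) float64 array of (x, y, z) coordinates. ``source``
    is a free-form provenance tag (file path, "synthetic", ...).
    """

    xyz: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.xyz, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"point cloud must be (N, 3), got shape {arr.shape}")
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("point cloud contains non-finite coordinates")
        object.__setattr__(self, "xyz", arr)

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the cloud."""
        if len(self) == 0:
            raise ValueError("empty point cloud has no bounds")
        return (
            float(self.x.min()),
            float(self.y.min()),
            float(self.x.max()),
            float(self.y.max()),
        )


@dataclass
class RasterGrid:
    """A single-band north-up raster.

    ``origin`` is the (x, y) of the grid's top-left corner; row 0 is the
    northernmost row. The value of cell (r, c) is attributed to the cell
    center at ``(origin_x + (c + 0.5) * cell_size,
    origin_y - (r + 0.5) * cell_size)``. Nodata cells are stored as NaN and
    excluded from all statistics.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    band: str = "other"  # one of DSM, DTM, CHM, other
    crs: str | None = None

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinate arrays (xs of shape n_cols, ys of shape n_rows)."""
        ox, oy = self.origin
        xs = ox + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = oy - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (n_rows, n_cols) meshes of cell-center x and y coordinates."""
        xs, ys = self.cell_centers()
        return np.meshgrid(xs, ys)

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )


def grid_for_bounds(
    bounds: tuple[float, float, float, float],
    cell_size: float,
    snap: float = 0.5,
) -> RasterGrid:
    """Build an empty (all-nodata) grid covering ``bounds``.

    The origin is snapped outward to a multiple of ``snap`` so that grids of
    different resolutions produced for the same scene nest predictably.
    """
    xmin, ymin, xmax, ymax = bounds
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("bounds must have positive extent")
    ox = np.floor(xmin / snap) * snap
    oy = np.ceil(ymax / snap) * snap
    n_cols = int(np.ceil((xmax - ox) / cell_size))
    n_rows = int(np.ceil((oy - ymin) / cell_size))
    values = np.full((n_rows, n_cols), np.nan)
    return RasterGrid(origin=(float(ox), float(oy)), cell_size=cell_size, values=values)


def _cell_indices(x: np.ndarray, y: np.ndarray, cell: float) -> np.ndarray:
    """Flattened integer cell ids for points binned on a ``cell``-sized lattice."""
    cx = np.floor(x / cell).astype(np.int64)
    cy = np.floor(y / cell).astype(np.int64)
    # Collision-free pairing: shift into non-negative range then row-major index.
    cx -= cx.min()
    cy -= cy.min()
    return cy * (cx.max() + 1) + cx


def _select_per_cell(cloud: PointCloud, cell: float, mode: str) -> PointCloud:
    """One point per occupied lattice cell: the min-z or max-z point.

    Ties on z break to the smallest x, then smallest y, for determinism.
    """
    if len(cloud) == 0:
        raise ValueError("empty point cloud")
    x, y, z = cloud.x, cloud.y, cloud.z
    ids = _cell_indices(x, y, cell)
    zkey = z if mode == "min" else -z
    # lexsort: last key is primary
    order = np.lexsort((y, x, zkey, ids))
    ids_sorted = ids[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = ids_sorted[1:] != ids_sorted[:-1]
    keep = order[first]
    keep.sort()  # preserve input ordering of survivors
    return PointCloud(cloud.xyz[keep], source=cloud.source)


def filter_lowest_points(cloud: PointCloud, filter_cell: float = 0.5) -> PointCloud:
    """Keep only the lowest point in every ``filter_cell`` x ``filter_cell`` cell.

    This is the ground-filtering step used before terrain-model
    triangulation: in a short-sward point cloud the lowest return in each
    half-meter cell is very likely a ground strike.
    """
    if filter_cell <= 0:
        raise ValueError("filter_cell must be positive")
    return _select_per_cell(cloud, filter_cell, "min")


def tin_interpolate(points: PointCloud, target: RasterGrid) -> RasterGrid:
    """Rasterize a point set through a Delaunay TIN onto ``target``'s grid.

    Each cell center inside the convex hull of the (x, y) points receives
    the linear (barycentric) interpolation of the containing triangle's
    vertex elevations; centers outside the hull get nodata. The
    interpolation is exact at the vertices and reproduces any plane.
    """
    if len(points) < 3:
        raise DegenerateGeometryError(
            f"need at least 3 points to triangulate, got {len(points)}"
        )
    try:
        interp = LinearNDInterpolator(points.xyz[:, :2], points.z)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point geometry: {exc}") from exc
    gx, gy = target.center_mesh()
    values = interp(gx, gy)
    return replace(target, values=values)


def build_dsm(cloud: PointCloud, resolution: float, snap: float = 0.5,
              grid: RasterGrid | None = None) -> RasterGrid:
    """Digital surface model: TIN of per-cell highest points.

    The highest point within each resolution-sized cell is selected before
    triangulation so that, in a mixed ground/canopy cloud, the surface
    follows the canopy top rather than interleaving ground strikes.
    """
    if grid is None:
        grid = grid_for_bounds(cloud.bounds(), resolution, snap=snap)
    maxima = _select_per_cell(cloud, resolution, "max")
    out = tin_interpolate(maxima, grid)
    out.band = "DSM"
    return out


def build_dtm(cloud: PointCloud, resolution: float, filter_cell: float = 0.5,
              snap: float = 0.5, grid: RasterGrid | None = None) -> RasterGrid:
    """Digital terrain model: TIN of lowest points per 0.5 m filter cell,
    rasterized at the same target resolution as the DSM."""
    if grid is None:
        grid = grid_for_bounds(cloud.bounds(), resolution, snap=snap)
    ground = filter_lowest_points(cloud, filter_cell)
    out = tin_interpolate(ground, grid)
    out.band = "DTM"
    return out


def build_chm(dsm: RasterGrid, dtm: RasterGrid, clamp_negative: bool = True) -> RasterGrid:
    """Canopy height model: cell-wise DSM minus DTM.

    Negative differences (surface below terrain, a TIN artifact) are
    clamped to zero by default since vegetation height cannot be negative;
    pass ``clamp_negative=False`` for diagnostics. Nodata in either input
    propagates to the output.
    """
    if not dsm.same_geometry(dtm):
        raise GridGeometryError("DSM and DTM grids do not share origin/cell_size/shape")
    values = dsm.values - dtm.values
    if clamp_negative:
        # keep NaN nodata; clamp only finite negatives
        values = np.where(np.isfinite(values), np.maximum(values, 0.0), np.nan)
    out = replace(dsm, values=values)
    out.band = "CHM"
    return out
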