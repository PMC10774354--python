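"""File formats: XYZ / LAS point clouds, single-band GeoTIFF rasters, tables.

The LAS reader/writer is a deliberately small implementation of the LAS
1.2 specification (point formats 0-3, reading only x/y/z with scale and
offset applied; writing point format 0 at 1 mm scale), sufficient for
exchanging photogrammetric point clouds with standard tooling.

GeoTIFF I/O goes through ``tifffile``: rasters are written as single-band
32-bit float with ModelPixelScale / ModelTiepoint geo tags and a
GDAL_NODATA sentinel, and read back into the package's north-up
``RasterGrid`` convention. Multi-band and rotated-geotransform inputs are
rejected.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .heterogeneity import HeterogeneityMeasure, TransectGeometry
from .surfaces import PointCloud, RasterGrid
from .synthetic import SurveyRecord

__all__ = [
    "PointCloudFormatError",
    "RasterFormatError",
    "read_point_cloud",
    "write_point_cloud",
    "read_xyz",
    "write_xyz",
    "read_las",
    "write_las",
    "read_raster",
    "write_raster",
    "read_transect_table",
    "write_transect_table",
    "read_survey_table",
    "write_survey_table",
    "write_hh_table",
]

NODATA_DEFAULT = -9999.0


class PointCloudFormatError(ValueError):
    pass


class RasterFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# XYZ text

def read_xyz(path: str | Path) -> PointCloud:
    """Read an ``x y z`` (whitespace- or comma-delimited) text point cloud."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.replace(",", " ").split()
            if len(parts) < 3:
                raise PointCloudFormatError(
                    f"{path.name}: line {lineno}: expected 3 fields, got {len(parts)}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise PointCloudFormatError(
                    f"{path.name}: line {lineno}: {exc}"
                ) from exc
    if not rows:
        raise PointCloudFormatError(f"{path.name}: no points found")
    return PointCloud(np.array(rows, dtype=np.float64), source=str(path))


def write_xyz(cloud: PointCloud, path: str | Path) -> None:
    np.savetxt(path, cloud.xyz, fmt="%.6f")


# ---------------------------------------------------------------------------
# LAS binary (1.2, point formats 0-3)

_LAS_HEADER_SIZE = 227
_LAS_POINT_SIZES = {0: 20, 1: 28, 2: 26, 3: 34}


def read_las(path: str | Path) -> PointCloud:
    """Read x/y/z from a LAS 1.x file (point formats 0-3)."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) < _LAS_HEADER_SIZE or data[:4] != b"LASF":
        raise PointCloudFormatError(f"{path.name}: not a LAS file")
    offset_to_points = struct.unpack_from("<I", data, 96)[0]
    fmt = struct.unpack_from("<B", data, 104)[0] & 0x3F
    rec_len = struct.unpack_from("<H", data, 105)[0]
    n_points = struct.unpack_from("<I", data, 107)[0]
    sx, sy, sz, ox, oy, oz = struct.unpack_from("<6d", data, 131)
    if fmt not in _LAS_POINT_SIZES:
        raise PointCloudFormatError(f"{path.name}: unsupported point format {fmt}")
    if n_points == 0:
        raise PointCloudFormatError(f"{path.name}: empty point cloud")
    body = data[offset_to_points : offset_to_points + n_points * rec_len]
    if len(body) < n_points * rec_len:
        raise PointCloudFormatError(f"{path.name}: truncated point records")
    raw = np.frombuffer(body, dtype=np.uint8).reshape(n_points, rec_len)
    ints = raw[:, :12].copy().view("<i4").reshape(n_points, 3)
    xyz = ints.astype(np.float64) * [sx, sy, sz] + [ox, oy, oz]
    return PointCloud(xyz, source=str(path))


def write_las(cloud: PointCloud, path: str | Path, scale: float = 0.001) -> None:
    """Write a LAS 1.2 point-format-0 file at the given coordinate scale (meters)."""
    if len(cloud) == 0:
        raise PointCloudFormatError("cannot write an empty point cloud")
    xyz = cloud.xyz
    offset = xyz.min(axis=0)
    ints = np.round((xyz - offset) / scale).astype("<i4")
    n = len(cloud)
    header = bytearray(_LAS_HEADER_SIZE)
    header[0:4] = b"LASF"
    struct.pack_into("<BB", header, 24, 1, 2)  # version 1.2
    struct.pack_into("<32s", header, 26, b"grasshh")
    struct.pack_into("<H", header, 94, _LAS_HEADER_SIZE)  # header size
    struct.pack_into("<I", header, 96, _LAS_HEADER_SIZE)  # offset to points
    struct.pack_into("<I", header, 100, 0)  # number of VLRs
    struct.pack_into("<B", header, 104, 0)  # point format 0
    struct.pack_into("<H", header, 105, _LAS_POINT_SIZES[0])
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<6d", header, 131, scale, scale, scale, *offset)
    mins = xyz.min(axis=0)
    maxs = xyz.max(axis=0)
    # header stores max/min as x_max, x_min, y_max, y_min, z_max, z_min
    struct.pack_into("<6d", header, 179,
                     maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2])
    records = np.zeros((n, _LAS_POINT_SIZES[0]), dtype=np.uint8)
    records[:, :12] = ints.view(np.uint8).reshape(n, 12)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(records.tobytes())


def read_point_cloud(path: str | Path, fmt: str | None = None) -> PointCloud:
    """Read a point cloud, sniffing LAS vs XYZ from the extension or content."""
    path = Path(path)
    if fmt is None:
        if path.suffix.lower() in {".las", ".laz"}:
            fmt = "las"
        else:
            fmt = "xyz"
    if fmt == "las":
        return read_las(path)
    if fmt == "xyz":
        return read_xyz(path)
    raise ValueError(f"unknown point cloud format {fmt!r}")


def write_point_cloud(cloud: PointCloud, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".las":
        write_las(cloud, path)
    else:
        write_xyz(cloud, path)


# ---------------------------------------------------------------------------
# GeoTIFF

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_TRANSFORM = 34264
_TAG_GDAL_NODATA = 42113


def write_raster(grid: RasterGrid, path: str | Path,
                 nodata: float = NODATA_DEFAULT) -> None:
    """Write a RasterGrid as a single-band float32 GeoTIFF.

    Internal NaN nodata is replaced by the ``nodata`` sentinel, which is
    recorded in the GDAL_NODATA tag; the geotransform is stored as
    ModelPixelScale + ModelTiepoint (north-up, no rotation).
    """
    values = np.where(np.isfinite(grid.values), grid.values, nodata).astype(np.float32)
    ox, oy = grid.origin
    cs = grid.cell_size
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    description = f"band={grid.band}"
    if grid.crs:
        description += f";crs={grid.crs}"
    tifffile.imwrite(path, values, extratags=extratags, description=description)


def read_raster(path: str | Path) -> RasterGrid:
    """Read a single-band north-up GeoTIFF into a RasterGrid."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise RasterFormatError(f"{path.name}: expected a single-band raster")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise RasterFormatError(f"{path.name}: expected a single-band raster")
        tags = page.tags
        if _TAG_TRANSFORM in tags:
            t = tags[_TAG_TRANSFORM].value
            if t[1] != 0 or t[4] != 0:
                raise RasterFormatError(
                    f"{path.name}: rotated geotransforms are not supported"
                )
            cell_x, cell_y = t[0], -t[5]
            ox, oy = t[3], t[7]
        elif _TAG_PIXEL_SCALE in tags and _TAG_TIEPOINT in tags:
            scale = tags[_TAG_PIXEL_SCALE].value
            tie = tags[_TAG_TIEPOINT].value
            cell_x, cell_y = scale[0], scale[1]
            # tiepoint maps raster (i, j, k) -> model (x, y, z)
            ox = tie[3] - tie[0] * cell_x
            oy = tie[4] + tie[1] * cell_y
        else:
            raise RasterFormatError(f"{path.name}: missing geotransform tags")
        if not np.isclose(cell_x, cell_y):
            raise RasterFormatError(f"{path.name}: non-square cells are not supported")
        values = page.asarray().astype(np.float64)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        band = "other"
        crs = None
        desc = tags.valueof(270) or ""
        for part in desc.split(";"):
            if part.startswith("band="):
                band = part[5:]
            elif part.startswith("crs="):
                crs = part[4:]
    if values.ndim != 2:
        raise RasterFormatError(f"{path.name}: expected a single-band raster")
    if nodata is not None:
        values = np.where(np.isclose(values, nodata), np.nan, values)
    return RasterGrid(origin=(float(ox), float(oy)), cell_size=float(cell_x),
                      values=values, band=band, crs=crs)


# ---------------------------------------------------------------------------
# Delimited tables

_TRANSECT_COLS = ["transect_id", "x_start", "y_start", "x_end", "y_end", "width_m"]


def write_transect_table(transects: list[TransectGeometry], path: str | Path) -> None:
    rows = [
        {
            "transect_id": t.transect_id,
            "x_start": t.start[0],
            "y_start": t.start[1],
            "x_end": t.end[0],
            "y_end": t.end[1],
            "width_m": t.width,
        }
        for t in transects
    ]
    pd.DataFrame(rows, columns=_TRANSECT_COLS).to_csv(path, index=False)


def read_transect_table(path: str | Path) -> list[TransectGeometry]:
    df = pd.read_csv(path)
    missing = set(_TRANSECT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"transect table missing columns: {sorted(missing)}")
    return [
        TransectGeometry(
            transect_id=str(r.transect_id),
            start=(float(r.x_start), float(r.y_start)),
            end=(float(r.x_end), float(r.y_end)),
            width=float(r.width_m),
        )
        for r in df.itertuples()
    ]


def write_survey_table(surveys: list[SurveyRecord], path: str | Path) -> None:
    from .analysis import surveys_to_frame

    surveys_to_frame(surveys).to_csv(path, index=False)


def read_survey_table(path: str | Path) -> list[SurveyRecord]:
    df = pd.read_csv(path)
    required = {"transect_id", "flower_richness", "bee_richness", "bee_abundance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survey table missing columns: {sorted(missing)}")
    return [
        SurveyRecord(
            transect_id=str(r.transect_id),
            flower_richness=int(r.flower_richness),
            bee_richness=int(r.bee_richness),
            bee_abundance=int(r.bee_abundance),
        )
        for r in df.itertuples()
    ]


def write_hh_table(measures: list[HeterogeneityMeasure], path: str | Path) -> None:
    from .analysis import measures_to_frame

    measures_to_frame(measures).to_csv(path, index=False)


def read_hh_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
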