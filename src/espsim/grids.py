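"""Gridded domain types and raster I/O.

All rasters live on a single projected coordinate reference system with
square cells. Row 0 is the top of the grid; ``origin`` is the map
coordinate of the upper-left corner of cell (0, 0). Areas are reported in
km² (``cell_count * cell_size**2 / 1e6``) or hm² (1 hm² = 0.01 km²).

Two file formats are supported: GeoTIFF (georeferencing carried in the
ModelPixelScale / ModelTiepoint tags) and the ESRI ASCII grid, a plain
text header-plus-matrix format. No reprojection is performed: all grids
entering an operation together must share one frame.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

#: Land-use class codes used throughout the package.
ARABLE, WOODLAND, GRASSLAND, WATER, CONSTRUCTION, UNUSED = 1, 2, 3, 4, 5, 6
LAND_USE_CODES = (ARABLE, WOODLAND, GRASSLAND, WATER, CONSTRUCTION, UNUSED)
LAND_USE_NAMES = {
    ARABLE: "arable",
    WOODLAND: "woodland",
    GRASSLAND: "grassland",
    WATER: "water",
    CONSTRUCTION: "construction",
    UNUSED: "unused",
}

# GeoTIFF tag ids used to persist the geotransform.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113


class RasterFormatError(ValueError):
    """Unreadable file or missing/invalid georeferencing metadata."""


@dataclass
class _Grid:
    cell_size: float
    origin: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self._data().shape

    def _data(self) -> np.ndarray:
        raise NotImplementedError

    def same_frame(self, other: "_Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell center, each shaped like the grid."""
        rows, cols = np.indices(self.shape)
        x = self.origin[0] + (cols + 0.5) * self.cell_size
        y = self.origin[1] - (rows + 0.5) * self.cell_size
        return x, y

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    @property
    def cell_area_hm2(self) -> float:
        return self.cell_size**2 / 1e4


@dataclass
class LandUseGrid(_Grid):
    """Categorical land-use raster over the six-class legend.

    ``codes`` holds integer class codes 1..6 (arable, woodland, grassland,
    water, construction, unused); ``nodata`` cells are excluded from every
    area computation and zonal statistic.
    """

    codes: np.ndarray = field(default=None)  # type: ignore[assignment]
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2 or self.codes.size == 0:
            raise ValueError("land-use grid must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("land-use codes must be integers")
        self.validate_codes()

    def validate_codes(self) -> None:
        valid = self.valid_mask()
        observed = np.unique(self.codes[valid])
        bad = set(observed.tolist()) - set(LAND_USE_CODES)
        if bad:
            raise ValueError(f"undeclared land-use codes present: {sorted(bad)}")

    def _data(self) -> np.ndarray:
        return self.codes

    def valid_mask(self) -> np.ndarray:
        return self.codes != self.nodata

    def class_mask(self, *codes: int) -> "BinaryMask":
        bits = np.isin(self.codes, codes) & self.valid_mask()
        return BinaryMask(cell_size=self.cell_size, origin=self.origin, bits=bits)

    def class_counts(self) -> dict[int, int]:
        valid = self.valid_mask()
        return {c: int(np.sum(self.codes[valid] == c)) for c in LAND_USE_CODES}

    def class_area_km2(self, code: int) -> float:
        return self.class_counts()[code] * self.cell_area_km2

    def copy(self) -> "LandUseGrid":
        return replace(self, codes=self.codes.copy())


@dataclass
class ContinuousGrid(_Grid):
    """Real-valued raster (driving factors, resistance, cost distance ...)."""

    values: np.ndarray = field(default=None)  # type: ignore[assignment]
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def _data(self) -> np.ndarray:
        return self.values

    def valid_mask(self) -> np.ndarray:
        if np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata


@dataclass
class BinaryMask(_Grid):
    """Boolean raster sharing the frame of its parent grid."""

    bits: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2 or self.bits.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")

    def _data(self) -> np.ndarray:
        return self.bits

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.cell_size, self.origin, self.bits | other.bits)

    def popcount(self) -> int:
        return int(self.bits.sum())

    def area_km2(self) -> float:
        return self.popcount() * self.cell_area_km2

    @classmethod
    def empty_like(cls, grid: _Grid) -> "BinaryMask":
        return cls(grid.cell_size, grid.origin, np.zeros(grid.shape, dtype=bool))


# ---------------------------------------------------------------------------
# I/O


def write_raster(grid: LandUseGrid | ContinuousGrid, path: str | Path) -> Path:
    """Write a grid as GeoTIFF (.tif/.tiff) or ESRI ASCII (anything else).

    Integer (categorical) grids are written with an integer sample type so
    the read/write round trip is bit-faithful.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        _write_geotiff(grid, path)
    else:
        _write_ascii(grid, path)
    return path


def read_raster(
    path: str | Path, kind: str = "auto"
) -> LandUseGrid | ContinuousGrid:
    """Read a GeoTIFF or ESRI ASCII grid.

    ``kind`` is ``"landuse"``, ``"continuous"`` or ``"auto"`` (integer data
    becomes a LandUseGrid, anything else a ContinuousGrid).
    """
    path = Path(path)
    if not path.exists():
        raise RasterFormatError(f"no such raster: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        data, cell_size, origin, nodata = _read_geotiff(path)
    else:
        data, cell_size, origin, nodata = _read_ascii(path)
    integral = np.issubdtype(data.dtype, np.integer)
    if kind == "landuse" or (kind == "auto" and integral):
        nd = int(nodata) if nodata is not None else -9999
        return LandUseGrid(cell_size, origin, data.astype(np.int64), nodata=nd)
    nd = float(nodata) if nodata is not None else float("nan")
    return ContinuousGrid(cell_size, origin, data.astype(float), nodata=nd)


def _write_geotiff(grid: LandUseGrid | ContinuousGrid, path: Path) -> None:
    data = grid._data()
    if isinstance(grid, LandUseGrid):
        data = data.astype(np.int32)
        nodata_str = str(int(grid.nodata))
    else:
        data = data.astype(np.float64)
        nodata_str = repr(float(grid.nodata))
    scale = (float(grid.cell_size), float(grid.cell_size), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(grid.origin[0]), float(grid.origin[1]), 0.0)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, scale, True),
        (_TAG_TIEPOINT, "d", 6, tiepoint, True),
        (_TAG_NODATA, "s", 0, nodata_str, True),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def _read_geotiff(path: Path):
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray()
            tags = page.tags
            if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
                raise RasterFormatError(f"{path}: missing geotransform tags")
            scale = tags[_TAG_PIXEL_SCALE].value
            tie = tags[_TAG_TIEPOINT].value
            nodata = None
            if _TAG_NODATA in tags:
                nodata = float(tags[_TAG_NODATA].value)
    except RasterFormatError:
        raise
    except Exception as exc:  # pragma: no cover - corrupt file path
        raise RasterFormatError(f"cannot read GeoTIFF {path}: {exc}") from exc
    return np.asarray(data), float(scale[0]), (float(tie[3]), float(tie[4])), nodata


def _write_ascii(grid: LandUseGrid | ContinuousGrid, path: Path) -> None:
    data = grid._data()
    rows, cols = data.shape
    nodata = grid.nodata
    # ESRI convention: corner is the LOWER-left of the grid.
    yll = grid.origin[1] - rows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {grid.origin[0]!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata}\n")
        if np.issubdtype(data.dtype, np.integer):
            np.savetxt(fh, data, fmt="%d")
        else:
            np.savetxt(fh, data, fmt="%.10g")


def _read_ascii(path: Path):
    known = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            m = re.match(r"^\s*([A-Za-z_]+)\s+(\S+)\s*$", line)
            if m and m.group(1).lower() in known and not data_lines:
                try:
                    header[m.group(1).lower()] = float(m.group(2))
                except ValueError as exc:
                    raise RasterFormatError(
                        f"{path}: bad header value in {line.strip()!r}"
                    ) from exc
            elif line.strip():
                data_lines.append(line)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"{path}: missing ASCII-grid header field {key}")
    try:
        data = np.loadtxt(data_lines, ndmin=2)
    except Exception as exc:
        raise RasterFormatError(f"{path}: unparseable grid body: {exc}") from exc
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (rows, cols):
        raise RasterFormatError(
            f"{path}: body shape {data.shape} != header ({rows}, {cols})"
        )
    cell = header["cellsize"]
    x0 = header.get("xllcorner", 0.0)
    y0 = header.get("yllcorner", 0.0) + rows * cell
    nodata = header.get("nodata_value")
    if np.all(data == np.round(data)):
        data = data.astype(np.int64)
    return data, cell, (x0, y0), nodata


# ---------------------------------------------------------------------------
# Distance


def euclidean_distance_field(mask: BinaryMask) -> ContinuousGrid:
    """Distance in meters from each cell center to the nearest true cell.

    True cells hold 0. Raises on an empty mask (the distance is undefined).
    """
    if not mask.bits.any():
        raise ValueError("distance field of an empty mask is undefined")
    dist = ndimage.distance_transform_edt(~mask.bits) * mask.cell_size
    return ContinuousGrid(mask.cell_size, mask.origin, dist)


def resample_nearest(
    grid: ContinuousGrid, factor: int
) -> ContinuousGrid:
    """Nearest-neighbor block replication (coarse grid -> fine grid)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    values = np.repeat(np.repeat(grid.values, factor, axis=0), factor, axis=1)
    return ContinuousGrid(grid.cell_size / factor, grid.origin, values, grid.nodata)
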