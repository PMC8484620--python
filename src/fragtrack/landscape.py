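"""Binary forest/non-forest landscapes and their I/O.

The unit of all raster computation is the :class:`BinaryLandscape`: a
2-D grid of forest / non-forest / nodata cells with square pixels in a
projected coordinate system.  Rasters are exchanged as ESRI ASCII grids
(``.asc``) — a plain-text, GDAL/ArcGIS-compatible format — with a JSON
sidecar (``<name>.aux.json``) carrying the CRS identifier, the epoch
year and, for class rasters, the class-code table and the parameters
that produced them.

Conventions
-----------
* pixel (row 0, col 0) is the top-left corner; ``origin`` is the map
  coordinate of that corner.
* pixel areas are ``count × pixel_size²`` — no geodesic correction, the
  workflow assumes an equal-area projected CRS.
* nodata cells are excluded from landscape area and treated as
  non-forest for fragmentation purposes (see ``nodata_as``).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import box, mapping
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

#: cell codes used throughout the package
FOREST = 1
NONFOREST = 0
NODATA = -1

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """Return the 3×3 binary structure for 4- or 8-connectivity."""
    if connectivity == 4:
        return _STRUCT_4
    if connectivity == 8:
        return _STRUCT_8
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity!r}")


class AlignmentError(ValueError):
    """Rasters participating in one analysis are not pixel-aligned."""


@dataclass(frozen=True)
class BinaryLandscape:
    """One epoch's forest/non-forest grid with georeferencing.

    Parameters
    ----------
    values
        2-D ``int8`` array over {FOREST, NONFOREST, NODATA}.
    pixel_size
        Side length of the (square) pixels in metres.
    origin
        ``(x, y)`` map coordinate of the top-left corner.
    crs_id
        Free-text identifier of the projected CRS (e.g. ``"EPSG:32645"``).
    epoch_year
        Year label of the epoch this raster represents.
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local"
    epoch_year: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("values must be a non-empty 2-D grid")
        if not np.isin(v, (FOREST, NONFOREST, NODATA)).all():
            raise ValueError("cells must be forest (1), nonforest (0) or nodata (-1)")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "values", np.ascontiguousarray(v, dtype=np.int8))

    # -- geometry ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def width_m(self) -> float:
        return self.shape[1] * self.pixel_size

    @property
    def height_m(self) -> float:
        return self.shape[0] * self.pixel_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent."""
        x0, y0 = self.origin
        return (x0, y0 - self.height_m, x0 + self.width_m, y0)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x/y map coordinates of every pixel center (1-D arrays per axis)."""
        x0, y0 = self.origin
        nrow, ncol = self.shape
        xs = x0 + (np.arange(ncol) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(nrow) + 0.5) * self.pixel_size
        return xs, ys

    # -- content -------------------------------------------------------
    def forest_mask(self, nodata_as: str = "nonforest") -> np.ndarray:
        """Boolean forest mask; nodata maps to False under either policy."""
        if nodata_as not in ("nonforest", "exclude"):
            raise ValueError(f"nodata_as must be 'nonforest' or 'exclude', got {nodata_as!r}")
        return self.values == FOREST

    @property
    def n_forest(self) -> int:
        return int((self.values == FOREST).sum())

    @property
    def n_nodata(self) -> int:
        return int((self.values == NODATA).sum())

    @property
    def forest_area_km2(self) -> float:
        return self.n_forest * self.pixel_size**2 / 1e6

    @property
    def landscape_area_km2(self) -> float:
        """Area of valid (non-nodata) cells in km²."""
        return (self.values.size - self.n_nodata) * self.pixel_size**2 / 1e6

    def with_values(self, values: np.ndarray, **kw) -> "BinaryLandscape":
        return replace(self, values=values, **kw)

    def is_aligned_with(self, other: "BinaryLandscape", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.pixel_size, other.pixel_size, rel_tol=0, abs_tol=tol)
            and math.isclose(self.origin[0], other.origin[0], rel_tol=0, abs_tol=tol)
            and math.isclose(self.origin[1], other.origin[1], rel_tol=0, abs_tol=tol)
        )


def require_aligned(*landscapes: BinaryLandscape) -> None:
    """Raise :class:`AlignmentError` unless all rasters are pixel-aligned."""
    first = landscapes[0]
    for other in landscapes[1:]:
        if not first.is_aligned_with(other):
            raise AlignmentError(
                "rasters are not pixel-aligned "
                f"(shape {first.shape} vs {other.shape}, origin {first.origin} vs "
                f"{other.origin}, pixel {first.pixel_size} vs {other.pixel_size}); "
                "resample explicitly before analysis"
            )


@dataclass(frozen=True)
class LandscapeSeries:
    """Ordered, pixel-aligned epochs with strictly increasing years."""

    epochs: tuple[BinaryLandscape, ...]

    def __post_init__(self) -> None:
        eps = tuple(self.epochs)
        if not eps:
            raise ValueError("series must contain at least one epoch")
        years = [e.epoch_year for e in eps]
        if any(y is None for y in years):
            raise ValueError("every epoch needs an epoch_year")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError(f"epoch years must be strictly increasing, got {years}")
        require_aligned(*eps)
        object.__setattr__(self, "epochs", eps)

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    def __getitem__(self, i):
        return self.epochs[i]

    @property
    def years(self) -> list[int]:
        return [e.epoch_year for e in self.epochs]

    @property
    def first(self) -> BinaryLandscape:
        return self.epochs[0]

    @property
    def last(self) -> BinaryLandscape:
        return self.epochs[-1]


@dataclass(frozen=True)
class GridSet:
    """Axis-aligned square analysis cells tiling a raster extent.

    Cells are numbered row-major from the top-left, starting at 1;
    boundary cells are clipped to the extent and may be partial.
    """

    cells: tuple[tuple[int, BaseGeometry], ...]
    cell_size: float
    n_cols: int
    n_rows: int
    origin: tuple[float, float]

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def ids(self) -> list[int]:
        return [cid for cid, _ in self.cells]

    @property
    def polygons(self) -> list[BaseGeometry]:
        return [p for _, p in self.cells]

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"cell_id": cid},
                "geometry": mapping(poly),
            }
            for cid, poly in self.cells
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )


@dataclass
class PointSet:
    """Point locations (e.g. conflict events) in the raster CRS."""

    x: np.ndarray
    y: np.ndarray
    year: np.ndarray | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("point coordinates must be finite")
        if self.year is not None:
            self.year = np.asarray(self.year)
            if self.year.shape != self.x.shape:
                raise ValueError("year must match point count")

    def __len__(self) -> int:
        return self.x.size

    def inside(self, landscape: BinaryLandscape) -> np.ndarray:
        """Boolean mask of points inside the raster extent (flag, don't drop)."""
        xmin, ymin, xmax, ymax = landscape.bounds
        return (self.x >= xmin) & (self.x < xmax) & (self.y > ymin) & (self.y <= ymax)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        d = {"x": self.x, "y": self.y}
        if self.year is not None:
            d["year"] = self.year
        pd.DataFrame(d).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PointSet":
        import pandas as pd

        df = pd.read_csv(path)
        for col in ("x", "y"):
            if col not in df.columns:
                raise ValueError(f"points CSV must have an '{col}' column")
        year = df["year"].to_numpy() if "year" in df.columns else None
        return cls(df["x"].to_numpy(), df["y"].to_numpy(), year=year)


# ---------------------------------------------------------------------------
# Raster I/O — ESRI ASCII grid + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".aux.json")


def write_ascii_grid(
    landscape: BinaryLandscape,
    path: str | Path,
    *,
    values: np.ndarray | None = None,
    nodata_value: int = -1,
    metadata: dict | None = None,
) -> Path:
    """Write a landscape (or an arbitrary integer grid on its frame) as
    an ESRI ASCII grid with a JSON sidecar.
    """
    path = Path(path)
    grid = landscape.values if values is None else np.asarray(values)
    if grid.shape != landscape.shape:
        raise ValueError("values grid must match landscape shape")
    nrow, ncol = grid.shape
    x0, y0 = landscape.origin
    header = (
        f"ncols {ncol}\n"
        f"nrows {nrow}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {(y0 - nrow * landscape.pixel_size)!r}\n"
        f"cellsize {landscape.pixel_size!r}\n"
        f"NODATA_value {nodata_value}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.astype(int), fmt="%d")
    side = {
        "crs_id": landscape.crs_id,
        "epoch_year": landscape.epoch_year,
        "codes": {"forest": FOREST, "nonforest": NONFOREST, "nodata": nodata_value},
    }
    if metadata:
        side.update(metadata)
    _sidecar_path(path).write_text(json.dumps(side, indent=2))
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Low-level reader: integer grid + header/sidecar metadata dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        grid = np.loadtxt(fh, dtype=int, ndmin=2)
    required = {"ncols", "nrows", "cellsize"}
    if not required <= header.keys():
        raise ValueError(f"malformed ASCII grid header in {path}: missing {required - header.keys()}")
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid shape {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])}) in {path}"
        )
    meta = dict(header)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return grid, meta


def read_binary_raster(
    path: str | Path,
    forest_codes: Iterable[int] = (1,),
    *,
    epoch_year: int | None = None,
) -> BinaryLandscape:
    """Read a single-band integer raster and binarize it.

    Cells whose value is in ``forest_codes`` become forest, the nodata
    value becomes nodata, and everything else non-forest.
    """
    forest_codes = frozenset(int(c) for c in forest_codes)
    if not forest_codes:
        raise ValueError("forest_codes must be non-empty")
    grid, meta = read_ascii_grid(path)
    nodata_value = int(meta.get("nodata_value", meta.get("codes", {}).get("nodata", -9999)))
    values = np.full(grid.shape, NONFOREST, dtype=np.int8)
    values[np.isin(grid, list(forest_codes))] = FOREST
    values[grid == nodata_value] = NODATA
    if not (values != NODATA).any():
        logger.warning("raster %s contains only nodata cells", path)
    nrow = int(meta["nrows"])
    cellsize = float(meta["cellsize"])
    x0 = float(meta.get("xllcorner", 0.0))
    y0 = float(meta.get("yllcorner", 0.0)) + nrow * cellsize
    crs = meta.get("crs_id")
    if crs is None:
        logger.warning("raster %s has no CRS metadata; assuming local coordinates", path)
        crs = "unknown"
    if epoch_year is None:
        epoch_year = meta.get("epoch_year")
    return BinaryLandscape(
        values, pixel_size=cellsize, origin=(x0, y0), crs_id=str(crs),
        epoch_year=None if epoch_year is None else int(epoch_year),
    )


# ---------------------------------------------------------------------------
# Raster operations
# ---------------------------------------------------------------------------

def apply_mmu(
    landscape: BinaryLandscape, min_area: float = 5000.0, connectivity: int = 8
) -> BinaryLandscape:
    """Enforce a minimum mapping unit: forest patches smaller than
    ``min_area`` m² (default 0.5 ha) are reclassified as non-forest.

    Patches are 8-connected by default.  The operation is idempotent.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if min_area == 0:
        return landscape
    forest = landscape.values == FOREST
    labels, n = ndimage.label(forest, structure=connectivity_structure(connectivity))
    if n == 0:
        return landscape
    counts = np.bincount(labels.ravel())
    pixel_area = landscape.pixel_size**2
    too_small = counts * pixel_area < min_area
    too_small[0] = False
    values = landscape.values.copy()
    values[too_small[labels]] = NONFOREST
    return landscape.with_values(values)


def resample_to(landscape: BinaryLandscape, target_pixel_size: float) -> BinaryLandscape:
    """Nearest-neighbour resampling to a new square pixel size.

    The georeferenced extent is preserved to within one target pixel
    (the output grid covers ``ceil(extent / target)`` pixels per axis,
    sampled at output-cell centers).
    """
    if not (target_pixel_size > 0):
        raise ValueError("target_pixel_size must be > 0")
    ratio = max(target_pixel_size / landscape.pixel_size, landscape.pixel_size / target_pixel_size)
    if ratio > 100:
        raise ValueError(
            f"resampling factor {ratio:.0f}× exceeds 100; check the units of "
            f"target_pixel_size ({target_pixel_size} m vs {landscape.pixel_size} m)"
        )
    if target_pixel_size == landscape.pixel_size:
        return landscape
    nrow, ncol = landscape.shape
    new_nrow = max(1, math.ceil(nrow * landscape.pixel_size / target_pixel_size))
    new_ncol = max(1, math.ceil(ncol * landscape.pixel_size / target_pixel_size))
    # source index of each output-cell center, clipped to the grid
    rows = np.minimum(
        ((np.arange(new_nrow) + 0.5) * target_pixel_size / landscape.pixel_size).astype(int),
        nrow - 1,
    )
    cols = np.minimum(
        ((np.arange(new_ncol) + 0.5) * target_pixel_size / landscape.pixel_size).astype(int),
        ncol - 1,
    )
    values = landscape.values[np.ix_(rows, cols)]
    return replace(landscape, values=values, pixel_size=float(target_pixel_size))


def make_grid(landscape: BinaryLandscape, cell_size: float = 5000.0) -> GridSet:
    """Tile the raster extent with square analysis cells (default 5 km),
    anchored at the raster origin; boundary cells are clipped (partial).
    """
    if cell_size < landscape.pixel_size:
        raise ValueError("cell_size must be at least one pixel")
    xmin, ymin, xmax, ymax = landscape.bounds
    n_cols = math.ceil(landscape.width_m / cell_size)
    n_rows = math.ceil(landscape.height_m / cell_size)
    extent = box(xmin, ymin, xmax, ymax)
    cells = []
    cid = 1
    for iy in range(n_rows):
        top = ymax - iy * cell_size
        for ix in range(n_cols):
            left = xmin + ix * cell_size
            cell = box(left, top - cell_size, left + cell_size, top)
            cells.append((cid, cell.intersection(extent)))
            cid += 1
    return GridSet(
        cells=tuple(cells),
        cell_size=float(cell_size),
        n_cols=n_cols,
        n_rows=n_rows,
        origin=landscape.origin,
    )
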