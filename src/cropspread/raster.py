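"""Terrain-class rasters, friction surfaces and accumulated cost distances.

The terrain model is a single-band integer raster on a projected, square-cell
grid (units: kilometres).  Each cell carries a terrain-class index; a per-class
cost vector turns the raster into a friction surface, and
:func:`accumulate_cost` computes shortest weighted path distances from an
origin cell over the 16-direction (knight's move) stencil.

Rasters are read and written as ESRI ASCII grids — a plain-text format with a
six-line header — together with an optional legend CSV ``class_id,label``.
Real-world rasters (e.g. a reclassified terrestrial-ecoregion layer) must be
projected to square km cells before use; :func:`lonlat_to_xy` provides the
simple equirectangular projection used for the synthetic world.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._dijkstra import OFFSETS_LEN, OFFSETS_RC, grid_dijkstra

NODATA = -1
#: clamp floor for per-class costs; non-positive friction breaks shortest-path
#: semantics (it would mean infinite or negative local speed)
COST_FLOOR = 0.01


class RasterFormatError(ValueError):
    """Raised for malformed raster files or inconsistent legends."""


@dataclass(frozen=True)
class GridTransform:
    """Affine link between cell indices and projected map coordinates (km).

    ``x_ll``/``y_ll`` are the coordinates of the lower-left corner of the
    grid; row 0 is the northernmost row, as in ESRI ASCII grids.
    """

    x_ll: float
    y_ll: float
    cell_size: float
    n_rows: int
    n_cols: int

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_ll + (col + 0.5) * self.cell_size
        y = self.y_ll + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def xy_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Nearest containing cell; may fall outside the grid (caller checks)."""
        col = int(math.floor((x - self.x_ll) / self.cell_size))
        row = self.n_rows - 1 - int(math.floor((y - self.y_ll) / self.cell_size))
        return row, col

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


@dataclass
class ClassRaster:
    """Dense-indexed terrain-class raster.

    ``classes`` holds indices ``0..K-1`` (``NODATA`` = -1); ``legend`` maps
    each dense index to a human-readable label, ``raw_ids`` to the id used in
    the source file.
    """

    classes: np.ndarray
    transform: GridTransform
    legend: list[str] = field(default_factory=list)
    raw_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int32)
        if self.classes.ndim != 2:
            raise RasterFormatError("class raster must be 2-D")
        if self.transform.cell_size <= 0:
            raise RasterFormatError("cell size must be positive")
        k = self.n_classes
        valid = self.classes[self.classes != NODATA]
        if valid.size and (valid.min() < 0 or valid.max() >= k):
            raise RasterFormatError("class index outside 0..K-1")

    @property
    def n_rows(self) -> int:
        return self.classes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.classes.shape[1]

    @property
    def cell_size(self) -> float:
        return self.transform.cell_size

    @property
    def n_classes(self) -> int:
        return len(self.legend)

    def friction(self, costs: np.ndarray) -> np.ndarray:
        """Per-cell friction from a per-class cost vector; nodata -> inf."""
        costs = validate_costs(costs, self.n_classes)
        fric = np.full(self.classes.shape, np.inf)
        mask = self.classes != NODATA
        fric[mask] = costs[self.classes[mask]]
        return fric


@dataclass
class AccumSurface:
    """Accumulated weighted distance (km) from an origin cell."""

    dist: np.ndarray  # float64, inf = unreachable
    origin: tuple[int, int]
    transform: GridTransform


def validate_costs(costs: np.ndarray, n_classes: int) -> np.ndarray:
    costs = np.asarray(costs, dtype=np.float64)
    if costs.shape != (n_classes,):
        raise ValueError(f"cost vector must have length {n_classes}, got {costs.shape}")
    if np.any(~np.isfinite(costs)) or np.any(costs < COST_FLOOR):
        raise ValueError(f"all costs must be finite and >= {COST_FLOOR} (clamp upstream)")
    return costs


def clamp_costs(costs: np.ndarray) -> np.ndarray:
    """Clamp a raw cost vector to the floor; used after random init/mutation."""
    return np.maximum(np.asarray(costs, dtype=np.float64), COST_FLOOR)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridTransform, int]:
    """Parse an ESRI ASCII grid; returns (values, transform, nodata_value)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    idx = 0
    while idx < len(lines):
        parts = lines[idx].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            idx += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"{path}: missing header field '{key}'")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nodata = int(header.get("nodata_value", NODATA))
    body = "\n".join(lines[idx:])
    tokens = body.split()
    try:
        values = np.array(tokens, dtype=np.float64)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: non-numeric cell value ({exc})") from None
    if values.size != n_rows * n_cols:
        raise RasterFormatError(
            f"{path}: expected {n_rows * n_cols} cells, found {values.size}"
        )
    grid = values.reshape(n_rows, n_cols)
    transform = GridTransform(
        x_ll=header.get("xllcorner", 0.0),
        y_ll=header.get("yllcorner", 0.0),
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return grid, transform, nodata


def write_ascii_grid(
    path: str | Path, grid: np.ndarray, transform: GridTransform,
    nodata: int | float = NODATA, fmt: str = "%d",
) -> None:
    header = (
        f"ncols {transform.n_cols}\n"
        f"nrows {transform.n_rows}\n"
        f"xllcorner {transform.x_ll}\n"
        f"yllcorner {transform.y_ll}\n"
        f"cellsize {transform.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt=fmt)


def load_class_raster(path: str | Path, legend_path: str | Path | None = None) -> ClassRaster:
    """Load a terrain-class raster, remapping ids to a dense 0..K-1 index.

    If ``legend_path`` is given it must be a CSV with columns
    ``class_id,label`` covering every id present in the raster.
    """
    grid, transform, nodata = read_ascii_grid(path)
    if not np.allclose(grid, np.round(grid)):
        raise RasterFormatError(f"{path}: class raster must contain integer ids")
    grid = grid.astype(np.int64)
    present = np.unique(grid[grid != nodata])

    if legend_path is not None:
        leg = pd.read_csv(legend_path)
        if not {"class_id", "label"} <= set(leg.columns):
            raise RasterFormatError(f"{legend_path}: legend needs columns class_id,label")
        raw_ids = leg["class_id"].astype(int).tolist()
        labels = leg["label"].astype(str).tolist()
        missing = set(present.tolist()) - set(raw_ids)
        if missing:
            raise RasterFormatError(
                f"{path}: raster ids {sorted(missing)} absent from legend {legend_path}"
            )
    else:
        raw_ids = present.tolist()
        labels = [f"class_{i}" for i in raw_ids]

    remap = {raw: dense for dense, raw in enumerate(raw_ids)}
    dense_grid = np.full(grid.shape, NODATA, dtype=np.int32)
    for raw, dense in remap.items():
        dense_grid[grid == raw] = dense
    return ClassRaster(classes=dense_grid, transform=transform, legend=labels, raw_ids=raw_ids)


def write_class_raster(path: str | Path, raster: ClassRaster,
                       legend_path: str | Path | None = None) -> None:
    raw = np.full(raster.classes.shape, NODATA, dtype=np.int64)
    for dense, raw_id in enumerate(raster.raw_ids):
        raw[raster.classes == dense] = raw_id
    write_ascii_grid(path, raw, raster.transform, nodata=NODATA, fmt="%d")
    if legend_path is not None:
        pd.DataFrame({"class_id": raster.raw_ids, "label": raster.legend}).to_csv(
            legend_path, index=False
        )


# ---------------------------------------------------------------------------
# Cost accumulation and sampling


def accumulate_cost(
    raster: ClassRaster, costs: np.ndarray, origin_cell: tuple[int, int]
) -> AccumSurface:
    """Dijkstra shortest weighted distances from ``origin_cell`` (row, col).

    Edge weight between adjacent cells a, b is
    ``euclid(a,b) * cell_size * (cost[class(a)] + cost[class(b)]) / 2`` with
    euclid in {1, √2, √5} for orthogonal, diagonal and knight moves.
    """
    row, col = origin_cell
    if not raster.transform.contains(row, col):
        raise ValueError(f"origin cell {origin_cell} outside raster")
    if raster.classes[row, col] == NODATA:
        raise ValueError(f"origin cell {origin_cell} is nodata")
    fric = raster.friction(costs)
    dist = grid_dijkstra(fric, raster.cell_size, row, col, OFFSETS_RC, OFFSETS_LEN)
    return AccumSurface(dist=dist, origin=(row, col), transform=raster.transform)


def sample_surface(
    surface: AccumSurface, sites: pd.DataFrame, x_col: str = "x", y_col: str = "y"
) -> pd.DataFrame:
    """Nearest-cell lookup of accumulated distance for each site.

    Returns a copy of ``sites`` with columns ``D_km`` (NaN if the site is
    outside the extent or unreachable) and ``D_status`` in
    {"ok", "outside_extent", "unreachable"}.
    """
    out = sites.copy()
    d_vals = np.full(len(out), np.nan)
    status = np.full(len(out), "ok", dtype=object)
    tr = surface.transform
    for i, (x, y) in enumerate(zip(out[x_col].to_numpy(), out[y_col].to_numpy())):
        row, col = tr.xy_to_cell(float(x), float(y))
        if not tr.contains(row, col):
            status[i] = "outside_extent"
            continue
        d = surface.dist[row, col]
        if not np.isfinite(d):
            status[i] = "unreachable"
            continue
        d_vals[i] = d
    out["D_km"] = d_vals
    out["D_status"] = status
    return out


def lonlat_to_xy(
    lon: np.ndarray, lat: np.ndarray, lon0: float = 0.0, lat0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection of lon/lat degrees to km about (lon0, lat0).

    Adequate for desk-scale synthetic worlds; real rasters should be
    projected with proper GIS tooling upstream.
    """
    r_earth = 6371.0
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = np.radians(lon - lon0) * r_earth * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * r_earth
    return x, y


def xy_to_lonlat(
    x: np.ndarray, y: np.ndarray, lon0: float = 0.0, lat0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`lonlat_to_xy`."""
    r_earth = 6371.0
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = np.degrees(x / (r_earth * math.cos(math.radians(lat0)))) + lon0
    lat = np.degrees(y / r_earth) + lat0
    return lon, lat
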