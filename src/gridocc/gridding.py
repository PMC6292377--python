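"""Planar grids over checklist locations and per-cell-per-year aggregation.

Checklist coordinates (WGS84 lat/lon) are projected to a planar equal-area
CRS, a square grid is overlaid on their bounding box, and detections plus
observer effort are aggregated into one row per (cell, year): the number of
checklists, summed effort hours, and a binary occupied flag per tracked
species.  The per-year proportion of surveyed cells that are occupied is
the descriptive series behind the trend model.

The projection is a spherical Albers equal-area conic (closed-form forward
and inverse), parameterised like the conterminous-US Albers so cells keep
comparable areas across the study region.  Cells use half-open intervals
``[low, high)`` on both axes, so cell assignment is a true partition.

Elevations can be sampled per point from a single-band raster in ESRI
ASCII grid format (a plain-text header plus a matrix of values).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Authalic Earth radius in meters (sphere of equal area to the WGS84 ellipsoid).
EARTH_RADIUS_M = 6371007.181


@dataclass(frozen=True)
class AlbersEqualArea:
    """Spherical Albers equal-area conic projection.

    Defaults follow the conterminous-US parameterisation (standard
    parallels 29.5 and 45.5, origin 23N 96W).  Coordinates are meters.
    """

    lat_1: float = 29.5
    lat_2: float = 45.5
    lat_0: float = 23.0
    lon_0: float = -96.0
    radius: float = EARTH_RADIUS_M

    @property
    def _n(self) -> float:
        return 0.5 * (math.sin(math.radians(self.lat_1)) + math.sin(math.radians(self.lat_2)))

    @property
    def _c(self) -> float:
        s1 = math.sin(math.radians(self.lat_1))
        return math.cos(math.radians(self.lat_1)) ** 2 + 2 * self._n * s1

    @property
    def _rho0(self) -> float:
        return self.radius * math.sqrt(self._c - 2 * self._n * math.sin(math.radians(self.lat_0))) / self._n

    def forward(self, lon, lat):
        """Project lon/lat degrees to planar (x, y) meters."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        n, c, rho0 = self._n, self._c, self._rho0
        under = c - 2 * n * np.sin(np.radians(lat))
        if np.any(under < 0):
            raise ValueError("latitude outside the validity range of this projection")
        rho = self.radius * np.sqrt(under) / n
        theta = n * np.radians(lon - self.lon_0)
        return rho * np.sin(theta), rho0 - rho * np.cos(theta)

    def inverse(self, x, y):
        """Invert planar (x, y) meters back to lon/lat degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n, c, rho0 = self._n, self._c, self._rho0
        rho = np.hypot(x, rho0 - y)
        theta = np.arctan2(x, rho0 - y)
        lat = np.degrees(np.arcsin((c - (rho * n / self.radius) ** 2) / (2 * n)))
        lon = self.lon_0 + np.degrees(theta / n)
        return lon, lat

    def to_dict(self) -> dict:
        return {
            "type": "albers_equal_area_spherical",
            "lat_1": self.lat_1,
            "lat_2": self.lat_2,
            "lat_0": self.lat_0,
            "lon_0": self.lon_0,
            "radius": self.radius,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AlbersEqualArea":
        keys = ("lat_1", "lat_2", "lat_0", "lon_0", "radius")
        return cls(**{k: data[k] for k in keys if k in data})


DEFAULT_CRS = AlbersEqualArea()


def cell_side_m(cell_size_km: float, interpretation: str = "side") -> float:
    """Convert a grid-size setting in km to a cell side in meters.

    ``interpretation="side"`` (the conventional GIS reading of e.g. a
    "10 km grid") treats the number as the side length; ``"area"`` treats
    it as the cell area in km^2, giving side ``sqrt(area)``.
    """
    if cell_size_km <= 0:
        raise ValueError("cell size must be positive")
    if interpretation == "side":
        return cell_size_km * 1000.0
    if interpretation == "area":
        return math.sqrt(cell_size_km) * 1000.0
    raise ValueError("interpretation must be 'side' or 'area'")


@dataclass(frozen=True)
class GridSpec:
    """A square planar grid: origin at the lower-left, half-open cells."""

    crs: AlbersEqualArea
    origin_x: float
    origin_y: float
    cell_side_m: float
    n_cols: int
    n_rows: int

    def __post_init__(self):
        if self.cell_side_m <= 0:
            raise ValueError("cell_side_m must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    def index_of(self, x, y):
        """Cell (col, row) of projected points, half-open ``[low, high)``.

        Pure lattice arithmetic in grid CRS meters; no bounds checking.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_side_m).astype(int)
        row = np.floor((y - self.origin_y) / self.cell_side_m).astype(int)
        return col, row

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) in grid CRS meters."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_side_m,
            self.origin_y + self.n_rows * self.cell_side_m,
        )

    def to_dict(self) -> dict:
        return {
            "crs": self.crs.to_dict(),
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "cell_side_m": self.cell_side_m,
            "n_cols": self.n_cols,
            "n_rows": self.n_rows,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GridSpec":
        return cls(
            crs=AlbersEqualArea.from_dict(data["crs"]),
            origin_x=data["origin_x"],
            origin_y=data["origin_y"],
            cell_side_m=data["cell_side_m"],
            n_cols=data["n_cols"],
            n_rows=data["n_rows"],
        )


def make_grid(
    lons,
    lats,
    cell_size_km: float,
    crs: AlbersEqualArea | None = None,
    interpretation: str = "side",
) -> GridSpec:
    """Build a grid covering the projected bounding box of the points.

    The origin is the lower-left corner of the bounding box *snapped down*
    to the canonical lattice of whole multiples of the cell side, and the
    extent is expanded upward/rightward to whole cells, so every point
    falls inside a cell under the half-open convention.  Snapping makes
    cell boundaries independent of the exact point minimum (adding or
    removing a checklist cannot shift every boundary) and makes grids of
    nested cell sizes (10 km and 5 km) share boundaries exactly.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.size == 0:
        raise ValueError("need at least one point to build a grid")
    crs = crs or DEFAULT_CRS
    side = cell_side_m(cell_size_km, interpretation)
    x, y = crs.forward(lons, lats)
    origin_x = float(np.floor(x.min() / side) * side)
    origin_y = float(np.floor(y.min() / side) * side)
    n_cols = max(1, int(np.floor((x.max() - origin_x) / side)) + 1)
    n_rows = max(1, int(np.floor((y.max() - origin_y) / side)) + 1)
    return GridSpec(crs, origin_x, origin_y, side, n_cols, n_rows)


def assign_cells(checklists: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Map every checklist to the grid cell containing its point.

    Returns a DataFrame with columns ``checklist_id, cell_col, cell_row``.
    Cell indices follow ``floor((coord - origin) / side)`` with half-open
    intervals, so a point exactly on the origin lands in cell (0, 0) and a
    point on an interior boundary belongs to the upper/right cell.
    Points outside the grid extent raise, naming an offending checklist.
    """
    x, y = grid.crs.forward(
        checklists["longitude"].to_numpy(), checklists["latitude"].to_numpy()
    )
    col, row = grid.index_of(x, y)
    outside = (col < 0) | (col >= grid.n_cols) | (row < 0) | (row >= grid.n_rows)
    if outside.any():
        offender = checklists["checklist_id"].to_numpy()[outside][0]
        raise ValueError(
            f"{int(outside.sum())} checklist(s) fall outside the grid extent "
            f"(first: {offender!r})"
        )
    return pd.DataFrame(
        {
            "checklist_id": checklists["checklist_id"].to_numpy(),
            "cell_col": col,
            "cell_row": row,
        }
    )


def aggregate_cell_year(
    checklists: pd.DataFrame,
    detections: pd.DataFrame,
    assignment: pd.DataFrame,
    species_list: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate checklists and detections to one row per (cell, year).

    Returns ``(cell_year, per_year)``:

    ``cell_year``
        columns ``cell_col, cell_row, year, n_checklists, effort_hours``
        plus a boolean ``occupied_<species>`` per tracked species.  Rows
        exist only for (cell, year) combinations with at least one
        checklist; ``effort_hours`` is the summed checklist duration and a
        cell-year is occupied iff at least one of its checklists recorded
        the species.

    ``per_year``
        columns ``species, year, n_cells_surveyed, n_cells_occupied,
        proportion, percent`` where ``percent`` is the proportion as a
        percentage rounded to one decimal place.
    """
    assigned = checklists.merge(assignment, on="checklist_id", how="inner")
    if len(assigned) != len(checklists):
        raise ValueError("assignment must cover every checklist")
    assigned["year"] = pd.to_datetime(assigned["date"]).dt.year

    keys = ["cell_col", "cell_row", "year"]
    for species in species_list:
        rows = detections[detections["species"] == species]
        position = pd.Index(rows["checklist_id"]).get_indexer(assigned["checklist_id"])
        if (position < 0).any():
            raise ValueError(f"detections are not zero-filled for {species!r}")
        assigned[f"occupied_{species}"] = rows["present"].to_numpy()[position]

    aggregations = {
        "n_checklists": ("checklist_id", "size"),
        "effort_hours": ("duration_hours", "sum"),
    }
    for species in species_list:
        aggregations[f"occupied_{species}"] = (f"occupied_{species}", "max")
    cell_year = assigned.groupby(keys, as_index=False).agg(**aggregations)
    for species in species_list:
        cell_year[f"occupied_{species}"] = cell_year[f"occupied_{species}"].astype(bool)

    per_year_rows = []
    surveyed = cell_year.groupby("year").size()
    for species in species_list:
        occupied = cell_year.groupby("year")[f"occupied_{species}"].sum()
        for year in surveyed.index:
            n_surveyed = int(surveyed[year])
            n_occupied = int(occupied[year])
            per_year_rows.append(
                {
                    "species": species,
                    "year": int(year),
                    "n_cells_surveyed": n_surveyed,
                    "n_cells_occupied": n_occupied,
                    "proportion": n_occupied / n_surveyed,
                    "percent": round(100.0 * n_occupied / n_surveyed, 1),
                }
            )
    per_year = pd.DataFrame(per_year_rows)
    return cell_year, per_year


def occupancy_percent(n_occupied: int, n_surveyed: int) -> float:
    """Occupied share of surveyed cells as a percentage, 1 decimal place."""
    if n_surveyed <= 0:
        raise ValueError("n_surveyed must be positive")
    return round(100.0 * n_occupied / n_surveyed, 1)


# ---------------------------------------------------------------------------
# Elevation sampling


@dataclass(frozen=True)
class AsciiGrid:
    """Single-band raster in ESRI ASCII grid layout.

    ``data`` is (nrows, ncols) with row 0 the NORTH edge, as in the file
    format; ``xll``/``yll`` are the coordinates of the lower-left corner of
    the lower-left cell, ``cellsize`` the square cell side, all in the
    raster's own coordinate units (geographic degrees for a lat/lon DEM).
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @classmethod
    def read(cls, path) -> "AsciiGrid":
        header: dict[str, float] = {}
        with open(path) as handle:
            position = 0
            for _ in range(6):
                position = handle.tell()
                line = handle.readline()
                key, _, value = line.strip().partition(" ")
                key = key.lower()
                if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                    header[key] = float(value)
                else:
                    handle.seek(position)
                    break
            data = np.loadtxt(handle, dtype=float, ndmin=2)
        if data.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("raster body does not match ncols/nrows header")
        return cls(
            data=data,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cellsize=header["cellsize"],
            nodata=header.get("nodata_value", -9999.0),
        )

    def write(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(f"ncols {self.ncols}\n")
            handle.write(f"nrows {self.nrows}\n")
            handle.write(f"xllcorner {float(self.xll)!r}\n")
            handle.write(f"yllcorner {float(self.yll)!r}\n")
            handle.write(f"cellsize {float(self.cellsize)!r}\n")
            handle.write(f"NODATA_value {float(self.nodata)!r}\n")
            np.savetxt(handle, self.data, fmt="%.6g")


def sample_elevation(lons, lats, raster: AsciiGrid) -> np.ndarray:
    """Nearest-cell raster value for each point; NaN outside or at no-data.

    Points and raster must share a coordinate system.  Out-of-bounds points
    produce a warning and a missing value rather than an error.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    col = np.floor((lons - raster.xll) / raster.cellsize).astype(int)
    # row index from the top: the top edge is yll + nrows * cellsize
    row = np.floor((raster.yll + raster.nrows * raster.cellsize - lats) / raster.cellsize).astype(int)
    # a point exactly on the top edge belongs to the top row
    row = np.where((lats == raster.yll + raster.nrows * raster.cellsize), 0, row)
    outside = (col < 0) | (col >= raster.ncols) | (row < 0) | (row >= raster.nrows)
    if outside.any():
        logger.warning("%d point(s) outside the raster bounds", int(outside.sum()))
    values = np.full(lons.shape, np.nan)
    inside = ~outside
    values[inside] = raster.data[row[inside], col[inside]]
    values[values == raster.nodata] = np.nan
    return values


def elevation_summary(elevations: pd.DataFrame) -> pd.DataFrame:
    """Median and range of elevation per region label.

    ``elevations`` needs columns ``region`` and ``elevation_m``; missing
    values are ignored and groups with no valid value are omitted with a
    warning.  The median of an even-sized group is the mean of the central
    pair (the usual order-statistic definition).
    """
    rows = []
    for region, group in elevations.groupby("region"):
        values = group["elevation_m"].dropna()
        if values.empty:
            logger.warning("region %r has no valid elevations; omitted", region)
            continue
        rows.append(
            {
                "region": region,
                "n": int(len(values)),
                "median_m": float(values.median()),
                "min_m": float(values.min()),
                "max_m": float(values.max()),
            }
        )
    return pd.DataFrame(rows, columns=["region", "n", "median_m", "min_m", "max_m"])
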