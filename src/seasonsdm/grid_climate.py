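"""Spatial grid definition and monthly climate climatologies.

The study frame is a regular latitude/longitude raster (default 0.5 deg cells).
All climate predictors live on this frame as per-month climatologies: for each
variable and calendar month, the multi-year mean field over the analysis period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: CMIP6 monthly surface variables used as default predictors: minimum / mean /
#: maximum near-surface temperature, specific and relative humidity, evaporation,
#: downwelling shortwave and longwave radiation, wind speed, precipitation and
#: cloud cover.
DEFAULT_VARIABLES: tuple[str, ...] = (
    "tasmin", "tasmean", "tasmax", "huss", "hurs", "evapsbl",
    "rsds", "rlds", "sfcwind", "pr", "clt",
)


class GridError(ValueError):
    """Raised for points outside the grid or inconsistent raster shapes."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid; row 0 at the southern edge, col 0 at the western edge.

    Cells are half-open intervals ``[edge, edge + cell_size)`` on both axes;
    points on the exact upper extent boundary belong to the last cell.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    cell_size: float = 0.5

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise GridError("grid extent must satisfy lat_min < lat_max and lon_min < lon_max")
        if self.cell_size <= 0:
            raise GridError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def n_cols(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def to_dict(self) -> dict:
        return {
            "lat_min": self.lat_min, "lat_max": self.lat_max,
            "lon_min": self.lon_min, "lon_max": self.lon_max,
            "cell_size": self.cell_size,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSpec":
        return cls(d["lat_min"], d["lat_max"], d["lon_min"], d["lon_max"], d["cell_size"])


def cell_of(lat, lon, grid: GridSpec):
    """Map coordinates to 0-based (row, col) cell indices.

    Accepts scalars or arrays.  Points exactly on the upper extent boundary are
    assigned to the last row/column; anything outside raises :class:`GridError`
    naming the offending coordinate.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(lat < grid.lat_min) or np.any(lat > grid.lat_max):
        bad = np.asarray(lat)[(lat < grid.lat_min) | (lat > grid.lat_max)]
        raise GridError(f"latitude {np.ravel(bad)[0]} outside extent [{grid.lat_min}, {grid.lat_max}]")
    if np.any(lon < grid.lon_min) or np.any(lon > grid.lon_max):
        bad = np.asarray(lon)[(lon < grid.lon_min) | (lon > grid.lon_max)]
        raise GridError(f"longitude {np.ravel(bad)[0]} outside extent [{grid.lon_min}, {grid.lon_max}]")
    row = np.floor((lat - grid.lat_min) / grid.cell_size).astype(int)
    col = np.floor((lon - grid.lon_min) / grid.cell_size).astype(int)
    row = np.minimum(row, grid.n_rows - 1)
    col = np.minimum(col, grid.n_cols - 1)
    if row.ndim == 0:
        return int(row), int(col)
    return row, col


def cell_center(row, col, grid: GridSpec):
    """Return (lat, lon) of cell centers; inverse of :func:`cell_of` on indices."""
    lat = grid.lat_min + (np.asarray(row) + 0.5) * grid.cell_size
    lon = grid.lon_min + (np.asarray(col) + 0.5) * grid.cell_size
    return lat, lon


@dataclass
class ClimateStack:
    """Per-(variable, month) climatology rasters for one period/scenario.

    ``values`` has shape (n_variables, 12, n_rows, n_cols); ``valid`` marks cells
    with usable data (ocean / no-data cells are False and samples falling there
    are rejected at feature-assembly time).  Units are opaque metadata; no
    conversion is ever applied.
    """

    grid: GridSpec
    variables: tuple[str, ...]
    values: np.ndarray
    valid: np.ndarray | None = None
    period_label: str = "historical"
    scenario_label: str = ""
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        expected = (len(self.variables), 12, *self.grid.shape)
        if self.values.shape != expected:
            raise GridError(f"values shape {self.values.shape} != expected {expected}")
        if self.valid is None:
            self.valid = ~np.any(np.isnan(self.values), axis=(0, 1))
        if self.valid.shape != self.grid.shape:
            raise GridError("validity mask does not conform to grid")

    def var_index(self, variable: str) -> int:
        try:
            return self.variables.index(variable)
        except ValueError:
            raise LookupError(
                f"variable {variable!r} not in stack; available: {list(self.variables)}"
            ) from None

    def monthly(self, variable: str, month: int) -> np.ndarray:
        """Raster of the month-``month`` (1..12) climatology of ``variable``."""
        if not 1 <= month <= 12:
            raise ValueError(f"month must be in 1..12, got {month}")
        return self.values[self.var_index(variable), month - 1]

    def copy(self) -> "ClimateStack":
        return ClimateStack(self.grid, self.variables, self.values.copy(),
                            self.valid.copy(), self.period_label,
                            self.scenario_label, dict(self.units))


def monthly_climatology(
    monthly_series: Mapping[tuple[int, int], np.ndarray],
    years: Iterable[int],
) -> dict[int, np.ndarray]:
    """Average per-(year, month) rasters into 12 per-month mean rasters.

    Every (year, month) combination in ``years`` x 1..12 must be present and all
    rasters must share one shape.  NaN (missing) cells propagate as NaN.
    """
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    shape = None
    out: dict[int, np.ndarray] = {}
    for month in range(1, 13):
        acc = None
        for year in years:
            if (year, month) not in monthly_series:
                raise ValueError(f"missing raster for year={year}, month={month}")
            r = np.asarray(monthly_series[(year, month)], dtype=float)
            if shape is None:
                shape = r.shape
            elif r.shape != shape:
                raise GridError(f"raster shape {r.shape} inconsistent with {shape}")
            acc = r.copy() if acc is None else acc + r
        out[month] = acc / len(years)
    return out


def regrid_nearest(src_values: np.ndarray, src_grid: GridSpec, dst_grid: GridSpec) -> np.ndarray:
    """Nearest-neighbour regrid of a (..., rows, cols) raster between grids."""
    dst_lat, _ = cell_center(np.arange(dst_grid.n_rows), 0, dst_grid)
    _, dst_lon = cell_center(0, np.arange(dst_grid.n_cols), dst_grid)
    src_lat, _ = cell_center(np.arange(src_grid.n_rows), 0, src_grid)
    _, src_lon = cell_center(0, np.arange(src_grid.n_cols), src_grid)
    row_idx = np.abs(dst_lat[:, None] - src_lat[None, :]).argmin(axis=1)
    col_idx = np.abs(dst_lon[:, None] - src_lon[None, :]).argmin(axis=1)
    return src_values[..., row_idx[:, None], col_idx[None, :]]


# ---------------------------------------------------------------------------
# I/O: NetCDF (scipy backend), plain TIFF + JSON sidecar, internal stack format
# ---------------------------------------------------------------------------

def _grid_from_coords(lats: np.ndarray, lons: np.ndarray) -> GridSpec:
    dlat = float(np.median(np.diff(np.sort(lats))))
    dlon = float(np.median(np.diff(np.sort(lons))))
    if not np.isclose(dlat, dlon, rtol=1e-6):
        raise GridError(f"anisotropic source grid (dlat={dlat}, dlon={dlon}) not supported")
    return GridSpec(float(lats.min() - dlat / 2), float(lats.max() + dlat / 2),
                    float(lons.min() - dlon / 2), float(lons.max() + dlon / 2), dlat)


def load_climate(
    paths: Sequence[str | Path],
    variables: Sequence[str] = DEFAULT_VARIABLES,
    grid: GridSpec | None = None,
    period_label: str = "historical",
    scenario_label: str = "",
) -> ClimateStack:
    """Load per-month climatologies for ``variables`` from NetCDF/TIFF files.

    Each NetCDF file may hold several variables, each with a 12-long leading
    month dimension; a TIFF file holds one variable as 12 pages and is
    accompanied by ``<file>.json`` with ``{"variable": ..., "grid": {...}}``.
    Sources are regridded to ``grid`` by nearest neighbour (no interpolation).
    The variable ordering of the output follows the request.
    """
    import xarray as xr

    found: dict[str, tuple[np.ndarray, GridSpec]] = {}
    available: list[str] = []
    for path in paths:
        path = Path(path)
        if path.suffix in {".nc", ".cdf", ".netcdf"}:
            with xr.open_dataset(path, engine="scipy") as ds:
                lats = ds["lat"].values
                lons = ds["lon"].values
                src_grid = _grid_from_coords(lats, lons)
                order_r = np.argsort(lats)
                order_c = np.argsort(lons)
                for name, da in ds.data_vars.items():
                    available.append(str(name))
                    if name in variables:
                        vals = np.asarray(da.values, dtype=float)
                        if vals.shape[0] != 12:
                            raise GridError(f"{path}:{name} has {vals.shape[0]} months, expected 12")
                        vals = vals[:, order_r][:, :, order_c]
                        found[str(name)] = (vals, src_grid)
        elif path.suffix in {".tif", ".tiff"}:
            import tifffile

            sidecar = path.with_suffix(path.suffix + ".json")
            if not sidecar.exists():
                raise GridError(f"TIFF {path} requires a JSON sidecar {sidecar} with grid info")
            meta = json.loads(sidecar.read_text())
            name = meta["variable"]
            available.append(name)
            if name in variables:
                vals = np.asarray(tifffile.imread(path), dtype=float)
                if vals.shape[0] != 12:
                    raise GridError(f"{path} has {vals.shape[0]} pages, expected 12 months")
                found[name] = (vals, GridSpec.from_dict(meta["grid"]))
        else:
            raise GridError(f"unsupported climate file format: {path}")

    missing = [v for v in variables if v not in found]
    if missing:
        raise LookupError(f"variables {missing} not found; available: {sorted(set(available))}")

    if grid is None:
        grid = found[variables[0]][1]
    out = np.empty((len(variables), 12, *grid.shape), dtype=float)
    for i, v in enumerate(variables):
        vals, src_grid = found[v]
        if src_grid == grid:
            out[i] = vals
        else:
            out[i] = regrid_nearest(vals, src_grid, grid)
    return ClimateStack(grid, tuple(variables), out,
                        period_label=period_label, scenario_label=scenario_label)


def save_stack(stack: ClimateStack, directory: str | Path) -> Path:
    """Serialize a stack as ``values.npz`` + ``meta.json`` sidecar in a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "values.npz", values=stack.values, valid=stack.valid)
    meta = {
        "grid": stack.grid.to_dict(),
        "variables": list(stack.variables),
        "months": list(range(1, 13)),
        "period_label": stack.period_label,
        "scenario_label": stack.scenario_label,
        "units": stack.units,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_stack(directory: str | Path) -> ClimateStack:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    with np.load(directory / "values.npz") as npz:
        values = npz["values"]
        valid = npz["valid"]
    return ClimateStack(GridSpec.from_dict(meta["grid"]), tuple(meta["variables"]),
                        values, valid, meta["period_label"], meta["scenario_label"],
                        meta.get("units", {}))
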