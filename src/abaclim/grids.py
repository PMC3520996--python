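"""Core raster data model and file I/O.

All stages of the pipeline exchange data as :class:`RasterGrid` objects:
regular geographic (lat/lon, decimal degrees) grids with cell-center
registration, a boolean sea mask, and NaN as the in-memory nodata
sentinel.  Latitude increases northward along axis 0 in memory regardless
of on-disk row order; file formats that store rows top-down (ESRI ASCII)
are flipped at the I/O boundary.

Supported on-disk formats are NetCDF (via xarray's scipy backend) and
plain-text ESRI ASCII grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import xarray as xr

__all__ = [
    "RasterGrid",
    "GridStack",
    "GridGeometry",
    "read_raster",
    "write_raster",
    "regrid_check",
]

#: tolerance (degrees) for geometry equality
GEOM_TOL = 1e-9


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular lat/lon grid, cell-center registered.

    ``lon_origin``/``lat_origin`` are the coordinates of the *center* of
    the lower-left (south-western) cell; ``resolution`` is degrees per
    cell, equal in both axes.
    """

    n_lat: int
    n_lon: int
    lon_origin: float
    lat_origin: float
    resolution: float

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def lons(self) -> np.ndarray:
        """Cell-center longitudes, west to east."""
        return self.lon_origin + self.resolution * np.arange(self.n_lon)

    def lats(self) -> np.ndarray:
        """Cell-center latitudes, south to north."""
        return self.lat_origin + self.resolution * np.arange(self.n_lat)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon2d, lat2d) arrays of shape ``(n_lat, n_lon)``."""
        return np.meshgrid(self.lons(), self.lats())


@dataclass
class RasterGrid:
    """A single-variable raster on a regular lat/lon grid.

    ``values`` has shape ``(n_lat, n_lon)`` with row 0 the southernmost
    row.  Cells where ``mask`` is False are land/invalid, carry NaN, and
    are excluded from every statistic.
    """

    values: np.ndarray
    geometry: GridGeometry
    mask: np.ndarray = None  # type: ignore[assignment]
    variable: str = "value"
    crs_note: str = "geographic lat/lon, decimal degrees, WGS84-like"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry {self.geometry.shape}"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have identical shape")
        # enforce the NaN sentinel on invalid cells
        self.values = np.where(self.mask, self.values, np.nan)

    # -- convenience ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.geometry.shape

    @property
    def resolution(self) -> float:
        return self.geometry.resolution

    def sea_values(self) -> np.ndarray:
        """1-D array of the valid (sea) cell values."""
        return self.values[self.mask]

    def sea_mean(self) -> float:
        v = self.sea_values()
        if v.size == 0:
            raise ValueError("no valid cells")
        return float(np.mean(v))

    def with_values(self, values: np.ndarray, variable: str | None = None) -> "RasterGrid":
        """New grid with the same geometry/mask and different values."""
        return RasterGrid(
            values=np.where(self.mask, values, np.nan),
            geometry=self.geometry,
            mask=self.mask.copy(),
            variable=variable if variable is not None else self.variable,
            crs_note=self.crs_note,
        )

    def copy(self) -> "RasterGrid":
        return RasterGrid(
            values=self.values.copy(),
            geometry=self.geometry,
            mask=self.mask.copy(),
            variable=self.variable,
            crs_note=self.crs_note,
        )


@dataclass
class GridStack:
    """Ordered collection of grids on identical geometry, with labels.

    Labels are arbitrary hashables — decade integers, scenario names,
    month names, model names, or tuples thereof.
    """

    grids: list[RasterGrid]
    labels: list

    def __post_init__(self) -> None:
        if len(self.grids) != len(self.labels):
            raise ValueError("one label per grid required")
        if self.grids:
            ref = self.grids[0]
            for g in self.grids[1:]:
                if not regrid_check(ref, g):
                    raise ValueError("all member grids must share geometry")
                if not np.array_equal(ref.mask, g.mask):
                    raise ValueError("all member grids must share the mask")

    def __len__(self) -> int:
        return len(self.grids)

    def __iter__(self) -> Iterator[tuple[object, RasterGrid]]:
        return iter(zip(self.labels, self.grids))

    def __getitem__(self, label) -> RasterGrid:
        try:
            return self.grids[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"label {label!r} not in stack") from None

    @property
    def geometry(self) -> GridGeometry:
        return self.grids[0].geometry


def regrid_check(a: RasterGrid, b: RasterGrid) -> bool:
    """True iff the two grids share shape, origin and resolution.

    Origins and resolution are compared to within 1e-9 degrees.
    """
    ga, gb = a.geometry, b.geometry
    return (
        ga.shape == gb.shape
        and abs(ga.lon_origin - gb.lon_origin) <= GEOM_TOL
        and abs(ga.lat_origin - gb.lat_origin) <= GEOM_TOL
        and abs(ga.resolution - gb.resolution) <= GEOM_TOL
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ASCII_NODATA = -9999.0


def write_raster(grid: RasterGrid, path: str | Path, format: str | None = None) -> None:
    """Write a grid to disk as ``netcdf`` or ``ascii-grid``.

    The format is inferred from the file suffix (.nc → netcdf, .asc →
    ascii-grid) when not given.  Masked cells are written as the format's
    nodata (NaN / _FillValue for NetCDF, a ``NODATA_value`` for ASCII).
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    try:
        if fmt == "netcdf":
            _write_netcdf(grid, path)
        else:
            _write_ascii(grid, path)
    except OSError as exc:
        raise OSError(f"cannot write raster to {path}: {exc}") from exc


def read_raster(path: str | Path, format: str | None = None) -> RasterGrid:
    """Read a grid from a ``netcdf`` or ``ascii-grid`` file.

    The returned grid's mask marks nodata cells invalid; geometry
    round-trips through :func:`write_raster`.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read raster: no such file {path}")
    fmt = _resolve_format(path, format)
    if fmt == "netcdf":
        return _read_netcdf(path)
    return _read_ascii(path)


def _resolve_format(path: Path, format: str | None) -> str:
    if format is None:
        suffix = path.suffix.lower()
        format = {".nc": "netcdf", ".nc4": "netcdf", ".asc": "ascii-grid"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer raster format from suffix {suffix!r}")
    if format == "geotiff":
        raise ValueError(
            "geotiff output is not supported in this build; use netcdf or ascii-grid"
        )
    if format not in ("netcdf", "ascii-grid"):
        raise ValueError(f"unknown raster format {format!r}")
    return format


def _write_netcdf(grid: RasterGrid, path: Path) -> None:
    g = grid.geometry
    da = xr.DataArray(
        grid.values,
        coords={"lat": g.lats(), "lon": g.lons()},
        dims=("lat", "lon"),
        name=grid.variable or "value",
        attrs={"crs_note": grid.crs_note, "resolution_deg": g.resolution},
    )
    da.to_netcdf(path, engine="scipy")


def _read_netcdf(path: Path) -> RasterGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        names = list(ds.data_vars)
        if not names:
            raise ValueError(f"format error: no data variable in {path}")
        da = ds[names[0]].load()
    if "lat" not in da.dims or "lon" not in da.dims:
        raise ValueError(f"format error: missing lat/lon coordinates in {path}")
    da = da.transpose("lat", "lon")
    lats = np.asarray(da["lat"].values, dtype=float)
    lons = np.asarray(da["lon"].values, dtype=float)
    values = np.asarray(da.values, dtype=float)
    if lats.size > 1 and lats[1] < lats[0]:  # stored north-down
        lats = lats[::-1]
        values = values[::-1, :]
    res = _infer_resolution(lons, lats, path)
    geom = GridGeometry(
        n_lat=lats.size, n_lon=lons.size,
        lon_origin=float(lons[0]), lat_origin=float(lats[0]), resolution=res,
    )
    return RasterGrid(values=values, geometry=geom, variable=str(da.name))


def _infer_resolution(lons: np.ndarray, lats: np.ndarray, path: Path) -> float:
    steps = []
    if lons.size > 1:
        steps.append(np.diff(lons))
    if lats.size > 1:
        steps.append(np.diff(lats))
    if not steps:
        raise ValueError(f"format error: cannot infer resolution of 1x1 grid {path}")
    steps = np.concatenate(steps)
    res = float(steps[0])
    if not np.allclose(steps, res, atol=1e-7):
        raise ValueError(f"format error: irregular coordinate spacing in {path}")
    return res


def _write_ascii(grid: RasterGrid, path: Path) -> None:
    g = grid.geometry
    # ESRI ASCII is corner-registered and stores rows north-down
    header = (
        f"ncols {g.n_lon}\n"
        f"nrows {g.n_lat}\n"
        f"xllcorner {g.lon_origin - g.resolution / 2:.10g}\n"
        f"yllcorner {g.lat_origin - g.resolution / 2:.10g}\n"
        f"cellsize {g.resolution:.10g}\n"
        f"NODATA_value {_ASCII_NODATA:g}\n"
    )
    out = np.where(grid.mask, grid.values, _ASCII_NODATA)[::-1, :]
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def _read_ascii(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value") and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required.issubset(header):
        missing = sorted(required - set(header))
        raise ValueError(f"format error: ASCII grid {path} missing header keys {missing}")
    n_lat, n_lon = int(header["nrows"]), int(header["ncols"])
    values = np.concatenate(rows).reshape(n_lat, n_lon)[::-1, :]
    nodata = header.get("nodata_value", _ASCII_NODATA)
    mask = values != nodata
    res = header["cellsize"]
    geom = GridGeometry(
        n_lat=n_lat, n_lon=n_lon,
        lon_origin=header["xllcorner"] + res / 2,
        lat_origin=header["yllcorner"] + res / 2,
        resolution=res,
    )
    return RasterGrid(values=np.where(mask, values, np.nan), geometry=geom, mask=mask,
                      variable=path.stem)
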