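"""Gridded climate data containers and plain-text raster I/O.

A :class:`ClimateStack` is a set of co-registered named layers on a regular
geographic grid (WGS84 semantics, degrees). Layers are stored as a single
(n_layers, n_rows, n_cols) float array with a shared validity mask; row 0 is
the southernmost row. Rasters are read and written as ESRI ASCII grids
(``.asc``) — the native raster format of the MaxEnt distribution-modelling
tool — one file per layer, with a small JSON sidecar naming the layers.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

NODATA_VALUE = -9999.0

#: default cell size: 5 arc-minutes, the WorldClim resolution used for
#: continental-scale bioclimatic modelling (~10 km at the equator)
DEFAULT_CELL_SIZE = 5.0 / 60.0


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid: ``origin`` is the lower-left (SW) corner."""

    n_rows: int
    n_cols: int
    cell_size: float = DEFAULT_CELL_SIZE
    origin_lon: float = -90.0
    origin_lat: float = -60.0
    crs_label: str = "WGS84"

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols); row 0 is southernmost."""
        lon = self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat = self.origin_lat + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given coordinates."""
        col = np.floor((np.asarray(lon, dtype=float) - self.origin_lon)
                       / self.cell_size).astype(int)
        row = np.floor((np.asarray(lat, dtype=float) - self.origin_lat)
                       / self.cell_size).astype(int)
        return row, col

    def contains_cell(self, row, col) -> np.ndarray:
        return ((np.asarray(row) >= 0) & (np.asarray(row) < self.n_rows)
                & (np.asarray(col) >= 0) & (np.asarray(col) < self.n_cols))


@dataclass
class ClimateStack:
    """Co-registered named predictor layers on a :class:`GridSpec`."""

    grid: GridSpec
    names: list[str]
    data: np.ndarray  # (n_layers, n_rows, n_cols), float
    mask: np.ndarray = field(default=None)  # (n_rows, n_cols) bool, True = valid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.names), self.grid.n_rows, self.grid.n_cols):
            raise ValueError("data shape does not match names/grid")
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_layers(self) -> int:
        return len(self.names)

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def valid_cell_indices(self) -> np.ndarray:
        """Flat indices (row * n_cols + col) of valid cells."""
        return np.flatnonzero(self.mask.ravel())

    def values_at_cells(self, flat_cells: np.ndarray,
                        names: list[str] | None = None) -> np.ndarray:
        """(n_cells, n_vars) predictor values at flat cell indices."""
        names = self.names if names is None else names
        idx = [self.names.index(n) for n in names]
        flat = self.data[idx].reshape(len(idx), -1)
        return flat[:, np.asarray(flat_cells, dtype=int)].T

    def values_at_lonlat(self, lon, lat, names: list[str] | None = None) -> np.ndarray:
        row, col = self.grid.cell_of(lon, lat)
        if not np.all(self.grid.contains_cell(row, col)):
            raise ValueError("coordinates fall outside the grid")
        return self.values_at_cells(row * self.grid.n_cols + col, names)

    def select(self, names: list[str]) -> "ClimateStack":
        idx = [self.names.index(n) for n in names]
        return ClimateStack(self.grid, list(names), self.data[idx], self.mask.copy())

    # -- plain-text raster I/O ------------------------------------------------

    def write_ascii(self, directory: str | Path, prefix: str = "stack") -> None:
        """One ESRI ASCII grid per layer plus a JSON sidecar listing names."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self.names:
            arr = np.where(self.mask, self.layer(name), NODATA_VALUE)
            write_ascii_grid(directory / f"{prefix}_{name}.asc", arr, self.grid)
        sidecar = {"prefix": prefix, "names": self.names,
                   "crs_label": self.grid.crs_label}
        (directory / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read_ascii(cls, directory: str | Path, prefix: str = "stack") -> "ClimateStack":
        directory = Path(directory)
        sidecar = json.loads((directory / f"{prefix}.json").read_text())
        layers = []
        for name in sidecar["names"]:
            arr, g = read_ascii_grid(directory / f"{prefix}_{name}.asc")
            layers.append(arr)
        data = np.stack(layers)
        mask = np.all(data != NODATA_VALUE, axis=0)
        grid = replace(g, crs_label=sidecar.get("crs_label", "WGS84"))
        return cls(grid, list(sidecar["names"]), data, mask)


def write_ascii_grid(path: str | Path, array: np.ndarray, grid: GridSpec) -> None:
    """ESRI ASCII grid; rows written north-to-south as the format requires."""
    header = (f"ncols {grid.n_cols}\nnrows {grid.n_rows}\n"
              f"xllcorner {grid.origin_lon}\nyllcorner {grid.origin_lat}\n"
              f"cellsize {grid.cell_size}\nNODATA_value {NODATA_VALUE}\n")
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in array[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
        key, val = lines[i].split()
        hdr[key.lower()] = float(val)
        i += 1
    rows = [np.array(ln.split(), dtype=float) for ln in lines[i:] if ln.strip()]
    array = np.stack(rows)[::-1]  # back to south-first row order
    grid = GridSpec(int(hdr["nrows"]), int(hdr["ncols"]), hdr["cellsize"],
                    hdr["xllcorner"], hdr["yllcorner"])
    return array, grid
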