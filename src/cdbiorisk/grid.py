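"""Regular raster container and ESRI ASCII grid input/output.

A :class:`GridField` stores one or more co-registered property rasters on
a regular grid with an explicit cell-center convention: ``origin`` is the
coordinate of the center of the lower-left cell, and array element
``[iy, ix]`` is the cell centered at ``origin + cell_size * (ix, iy)``
(row 0 is the southernmost row). ESRI ASCII files store rows north-first
with a corner-referenced origin; the reader/writer converts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GridField", "write_ascii_grid", "read_ascii_grid"]

NODATA = -9999.0


@dataclass
class GridField:
    nx: int
    ny: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    properties: dict[str, np.ndarray] = field(default_factory=dict)
    regions: np.ndarray | None = None  # optional (ny, nx) array of labels

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        for name, arr in self.properties.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.ny, self.nx):
                raise ValueError(
                    f"property {name!r} has shape {arr.shape}, "
                    f"expected {(self.ny, self.nx)}")
            self.properties[name] = arr
        if self.regions is not None:
            self.regions = np.asarray(self.regions, dtype=object)
            if self.regions.shape != (self.ny, self.nx):
                raise ValueError("regions must match the grid shape")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of shape (ny, nx)."""
        x = self.origin[0] + self.cell_size * np.arange(self.nx)
        y = self.origin[1] + self.cell_size * np.arange(self.ny)
        return np.meshgrid(x, y)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form table: one row per cell with x, y and every property."""
        xx, yy = self.cell_centers()
        data = {"x": xx.ravel(), "y": yy.ravel()}
        for name, arr in self.properties.items():
            data[name] = arr.ravel()
        if self.regions is not None:
            data["region"] = self.regions.ravel()
        return pd.DataFrame(data)

    def with_property(self, name: str, values: np.ndarray) -> "GridField":
        props = dict(self.properties)
        props[name] = np.asarray(values, dtype=float).reshape(self.ny, self.nx)
        return GridField(self.nx, self.ny, self.cell_size, self.origin,
                         props, self.regions)


def write_ascii_grid(path, grid: GridField, prop: str) -> None:
    """Write one property raster as an ESRI ASCII grid (NaN -> NODATA)."""
    arr = grid.properties[prop]
    half = grid.cell_size / 2.0
    lines = [
        f"ncols {grid.nx}",
        f"nrows {grid.ny}",
        f"xllcorner {grid.origin[0] - half!r}",
        f"yllcorner {grid.origin[1] - half!r}",
        f"cellsize {grid.cell_size!r}",
        f"NODATA_value {NODATA!r}",
    ]
    out = np.where(np.isnan(arr), NODATA, arr)
    for row in out[::-1]:  # north-first row order
        lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ascii_grid(path, name: str = "value") -> GridField:
    """Read an ESRI ASCII grid into a single-property GridField."""
    text = Path(path).read_text(encoding="utf-8").strip().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    nx, ny = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", NODATA)
    values = np.loadtxt(text[i:], dtype=float).reshape(ny, nx)[::-1]
    values = np.where(values == nodata, np.nan, values)
    origin = (header["xllcorner"] + cell / 2.0, header["yllcorner"] + cell / 2.0)
    return GridField(nx, ny, cell, origin, {name: values})
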