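"""Planar raster grids and ESRI ASCII grid I/O.

All rasters share one planar coordinate system in meters.  Values are
float arrays with NaN as the in-memory nodata mask; on disk the ESRI ASCII
convention is used (``NODATA_value -9999``).  Rows are stored north-to-south
(row 0 is the top of the grid), so the center of cell (0, 0) lies at
``(xll + cellsize/2, yll + nrows*cellsize - cellsize/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NODATA = -9999.0


@dataclass
class Grid:
    values: np.ndarray      # (nrows, ncols) float, NaN = nodata
    xll: float              # x of the lower-left corner
    yll: float              # y of the lower-left corner
    cellsize: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """True where the cell holds data."""
        return ~np.isnan(self.values)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.xll + (col + 0.5) * self.cellsize
        y = self.yll + (self.nrows - row - 0.5) * self.cellsize
        return x, y

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.floor((x - self.xll) / self.cellsize))
        row = int(np.floor((self.yll + self.nrows * self.cellsize - y)
                           / self.cellsize))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.cell_of(x, y)
        return float(self.values[r, c])

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of all cell-center coordinates."""
        cols = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        rows = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(cols, rows)

    def like(self, values: np.ndarray) -> "Grid":
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch")
        return Grid(values, self.xll, self.yll, self.cellsize)


def read_ascii(path) -> Grid:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        rows = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {"ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value", "xllcenter",
                                    "yllcenter"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key}")
    cell = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # center-registered header
        xll = header["xllcenter"] - cell / 2
        yll = header["yllcenter"] - cell / 2
    values = np.array([v for row in rows for v in row], dtype=float)
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", NODATA)
    values[values == nodata] = np.nan
    return Grid(values, xll, yll, cell)


def write_ascii(grid: Grid, path, fmt: str = "%.6g") -> None:
    vals = np.where(np.isnan(grid.values), NODATA, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll:.6f}\n")
        fh.write(f"yllcorner {grid.yll:.6f}\n")
        fh.write(f"cellsize {grid.cellsize:.6f}\n")
        fh.write(f"NODATA_value {NODATA:g}\n")
        for row in vals:
            fh.write(" ".join(fmt % v for v in row) + "\n")


@dataclass
class EnvGrid:
    """A named stack of co-registered environmental raster layers."""

    layers: dict[str, Grid]

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        if not grids:
            raise ValueError("EnvGrid needs at least one layer")
        ref = grids[0]
        for g in grids[1:]:
            if (g.values.shape != ref.values.shape or g.cellsize != ref.cellsize
                    or g.xll != ref.xll or g.yll != ref.yll):
                raise ValueError("all layers must share shape, origin and cell size")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def ref(self) -> Grid:
        return next(iter(self.layers.values()))

    @property
    def mask(self) -> np.ndarray:
        """True where every layer holds data."""
        m = np.ones(self.ref.values.shape, dtype=bool)
        for g in self.layers.values():
            m &= g.mask
        return m

    def stack(self) -> np.ndarray:
        """(nrows, ncols, n_vars) array."""
        return np.stack([self.layers[n].values for n in self.names], axis=-1)

    def extract(self, points: np.ndarray) -> np.ndarray:
        """Layer values at each (x, y) point; NaN rows where any layer is nodata."""
        points = np.asarray(points, dtype=float)
        out = np.empty((len(points), len(self.names)))
        for i, (x, y) in enumerate(points):
            r, c = self.ref.cell_of(x, y)
            out[i] = [self.layers[n].values[r, c] for n in self.names]
        return out
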