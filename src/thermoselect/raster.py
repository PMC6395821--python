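"""Lightweight raster container and plain-text (ESRI ASCII grid) I/O.

All layers in an analysis share one grid: row 0 is the northern edge,
column 0 the western edge, and a point (x, y) in world coordinates falls in
the half-open pixel ``[x0 + c*cs, x0 + (c+1)*cs) x (ytop - (r+1)*cs, ytop - r*cs]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass
class GridGeoref:
    """Affine georeference for a north-up, square-pixel grid."""

    x0: float  # west edge (xllcorner)
    y0: float  # south edge (yllcorner)
    cell_size: float
    nrows: int
    ncols: int

    @property
    def ytop(self) -> float:
        return self.y0 + self.nrows * self.cell_size

    def rowcol(self, x, y):
        """Map world coordinates to (row, col) of the containing pixel."""
        col = np.floor((np.asarray(x, float) - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.ytop - np.asarray(y, float)) / self.cell_size).astype(int)
        return row, col

    def xy(self, row, col):
        """Centre coordinates of pixel (row, col)."""
        x = self.x0 + (np.asarray(col, float) + 0.5) * self.cell_size
        y = self.ytop - (np.asarray(row, float) + 0.5) * self.cell_size
        return x, y

    def contains(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (
            (x >= self.x0)
            & (x < self.x0 + self.ncols * self.cell_size)
            & (y > self.y0)
            & (y <= self.ytop)
        )


@dataclass
class Raster:
    """A single 2-D layer on a shared grid."""

    data: np.ndarray
    georef: GridGeoref
    nodata: float = NODATA

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.georef.nrows, self.georef.ncols):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid "
                f"({self.georef.nrows}, {self.georef.ncols})"
            )

    @property
    def valid(self) -> np.ndarray:
        return ~np.isclose(self.data, self.nodata) & np.isfinite(self.data)

    def masked(self) -> np.ndarray:
        out = self.data.copy()
        out[~self.valid] = np.nan
        return out

    def sample(self, x, y):
        """Values at world coordinates; nodata outside the grid."""
        row, col = self.georef.rowcol(x, y)
        inside = (
            (row >= 0) & (row < self.georef.nrows) & (col >= 0) & (col < self.georef.ncols)
        )
        out = np.full(np.shape(row), self.nodata, dtype=float)
        out[inside] = self.data[row[inside], col[inside]]
        return out

    def like(self, data: np.ndarray) -> "Raster":
        return Raster(data, self.georef, self.nodata)


def write_ascii_grid(path, raster: Raster, fmt: str = "%.6f") -> None:
    """Write an ESRI ASCII grid (.asc), a plain-text raster interchange format."""
    g = raster.georef
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.x0:.6f}\n"
        f"yllcorner {g.y0:.6f}\n"
        f"cellsize {g.cell_size:.6f}\n"
        f"NODATA_value {raster.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data, fmt=fmt)


def read_ascii_grid(path) -> Raster:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        key = parts[0].lower()
        if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
            meta[key] = float(parts[1])
        else:
            break
    data = np.loadtxt(lines[i:])
    g = GridGeoref(
        x0=meta["xllcorner"],
        y0=meta["yllcorner"],
        cell_size=meta["cellsize"],
        nrows=int(meta["nrows"]),
        ncols=int(meta["ncols"]),
    )
    return Raster(data.reshape(g.nrows, g.ncols), g, meta.get("nodata_value", NODATA))


# land-cover category codes
LANDCOVER_CODES = {"meadow": 0, "wood": 1, "scree_rock": 2, "other": 3}


@dataclass
class CovariateStack:
    """Named, grid-aligned covariate rasters plus the shared georeference.

    Standard layers: ``dem`` (m), ``slope`` (degrees), ``cos_aspect``
    ([-1, 1], +1 north-facing), ``ruggedness`` (m), ``ndvi``,
    ``log_dist_trail`` (log metres), ``dist_safe`` (m), ``landcover``
    (categorical codes), ``safe_mask`` (0/1), ``sector`` (integer).
    """

    layers: dict = field(default_factory=dict)
    georef: GridGeoref = None
    nodata: float = NODATA

    def __post_init__(self):
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.georef.nrows, self.georef.ncols):
                raise ValueError(f"layer {name!r} shape mismatch")
            self.layers[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self):
        return list(self.layers)

    def raster(self, name: str) -> Raster:
        return Raster(self.layers[name], self.georef, self.nodata)

    @property
    def valid(self) -> np.ndarray:
        """Pixels valid in every layer."""
        ok = np.ones((self.georef.nrows, self.georef.ncols), dtype=bool)
        for arr in self.layers.values():
            ok &= ~np.isclose(arr, self.nodata) & np.isfinite(arr)
        return ok

    def sample(self, x, y, names=None):
        """Per-point layer values as a dict of arrays (nodata outside grid)."""
        names = names if names is not None else self.names
        return {n: self.raster(n).sample(x, y) for n in names}

    def write(self, directory, fmt: str = "%.6f") -> list:
        import os

        os.makedirs(directory, exist_ok=True)
        paths = []
        for name in sorted(self.layers):
            p = os.path.join(directory, f"{name}.asc")
            write_ascii_grid(p, self.raster(name), fmt=fmt)
            paths.append(p)
        return paths

    @classmethod
    def read(cls, directory) -> "CovariateStack":
        import glob
        import os

        layers = {}
        georef = None
        nodata = NODATA
        for p in sorted(glob.glob(os.path.join(directory, "*.asc"))):
            name = os.path.splitext(os.path.basename(p))[0]
            r = read_ascii_grid(p)
            layers[name] = r.data
            georef, nodata = r.georef, r.nodata
        if not layers:
            raise FileNotFoundError(f"no .asc layers under {directory}")
        return cls(layers, georef, nodata)
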