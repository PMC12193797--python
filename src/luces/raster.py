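"""Single-band raster grids and plain-text (ESRI ASCII) I/O.

The package works on rectangular single-band grids with a top-left origin
and square cells, in a fixed local projected CRS (metres).  Categorical
land-cover grids use the six-class integer coding in :data:`CLASS_CODES`;
continuous grids are float32/float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Land-cover class coding shared across the package (0 is reserved for nodata
#: in categorical rasters).
CLASS_CODES = {
    1: "cropland",
    2: "woodland",
    3: "grassland",
    4: "water",
    5: "built_up",
    6: "unused",
}
N_CLASSES = 6


@dataclass
class RasterGrid:
    """A single-band georeferenced grid.

    Parameters
    ----------
    values
        2-D array, row 0 at the northern (top) edge.
    cell_size_m
        Square cell edge length in metres; must be positive.
    nodata
        Sentinel for missing cells, or ``None`` when fully valid.
    categorical
        True for integer-coded land-cover grids (values in 1..6).
    origin
        (x, y) map coordinates of the top-left corner.
    """

    values: np.ndarray
    cell_size_m: float = 30.0
    nodata: float | int | None = None
    categorical: bool = False
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.categorical:
            valid = self.mask()
            vals = self.values[valid]
            if vals.size and not np.isin(vals, list(CLASS_CODES)).all():
                raise ValueError("categorical raster contains codes outside 1..6")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares."""
        return self.cell_size_m**2 / 1e4

    def mask(self) -> np.ndarray:
        """Boolean array of valid (non-nodata) cells."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        v = self.values
        if np.issubdtype(v.dtype, np.floating) and np.isnan(self.nodata):
            return ~np.isnan(v)
        return v != self.nodata

    def copy_with(self, values: np.ndarray, **kw) -> "RasterGrid":
        """New grid sharing this grid's georeferencing."""
        opts = dict(
            cell_size_m=self.cell_size_m,
            nodata=self.nodata,
            categorical=self.categorical,
            origin=self.origin,
        )
        opts.update(kw)
        return RasterGrid(values, **opts)

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_m, other.cell_size_m)
            and np.allclose(self.origin, other.origin)
        )

    def cell_centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates of every cell centre (row 0 = north)."""
        rows, cols = self.shape
        x0, y0 = self.origin
        cs = self.cell_size_m
        xs = x0 + (np.arange(cols) + 0.5) * cs
        ys = y0 - (np.arange(rows) + 0.5) * cs
        return np.meshgrid(xs, ys)


def require_aligned(*grids: RasterGrid) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if not ref.aligned_with(g):
            raise ValueError(
                f"rasters not aligned: {ref.shape}/{ref.cell_size_m} vs "
                f"{g.shape}/{g.cell_size_m}"
            )


def write_ascii(grid: RasterGrid, path: str | Path, fmt: str = "%.6g") -> None:
    """Write an ESRI ASCII grid (.asc), a plain-text single-band format."""
    path = Path(path)
    rows, cols = grid.shape
    nodata = grid.nodata if grid.nodata is not None else -9999
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {grid.origin[0]}\n"
        f"yllcorner {grid.origin[1] - rows * grid.cell_size_m}\n"
        f"cellsize {grid.cell_size_m}\n"
        f"NODATA_value {nodata}\n"
    )
    vals = grid.values
    if grid.nodata is None:
        body = vals
    else:
        body = vals
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%d" if grid.categorical else fmt)


def read_ascii(path: str | Path, categorical: bool = False) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    values = np.loadtxt(lines[n_header:])
    values = np.atleast_2d(values)
    if categorical:
        values = values.astype(np.int16)
    cs = header["cellsize"]
    nrows = int(header["nrows"])
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cs)
    return RasterGrid(
        values,
        cell_size_m=cs,
        nodata=header.get("nodata_value"),
        categorical=categorical,
        origin=origin,
    )
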