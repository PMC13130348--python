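"""Minimal planar raster container with ESRI-style ASCII grid I/O.

Rasters are stored with row 0 at the *top* (north), matching the on-disk
layout of ASCII grids. ``origin`` is the (x, y) of the lower-left corner of
the grid, in metres; cell centres are offset by half a cell from the edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    """A rectangular single-band raster on a planar grid.

    Parameters
    ----------
    values
        2-D array, shape (nrows, ncols); row 0 is the northernmost row.
        Integer arrays are treated as categorical (land cover classes),
        float arrays as continuous (elevation in metres).
    resolution_m
        Side length of a (square) cell in metres.
    origin
        (x, y) of the lower-left corner of the raster, metres.
    """

    values: np.ndarray
    resolution_m: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.resolution_m <= 0:
            raise ValueError("resolution_m must be positive")
        if not np.all(np.isfinite(self.values.astype(float))):
            raise ValueError("raster contains non-finite values")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of the centre of cell ``(row, col)``."""
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.resolution_m
        y = y0 + (self.nrows - row - 0.5) * self.resolution_m
        return x, y

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.ncols * self.resolution_m,
            y0 + self.nrows * self.resolution_m,
        )


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as a plain-text ESRI ASCII grid."""
    path = Path(path)
    x0, y0 = raster.origin
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {y0!r}\n"
        f"cellsize {raster.resolution_m!r}\n"
    )
    is_int = np.issubdtype(raster.values.dtype, np.integer)
    fmt = "%d" if is_int else "%.8g"
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt=fmt)


def read_ascii_grid(path: str | Path) -> Raster:
    """Read a plain-text ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(5):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape does not match header in {path}")
    if np.allclose(values, np.round(values)):
        values = values.astype(int)
    return Raster(
        values=values,
        resolution_m=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
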