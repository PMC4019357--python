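"""Minimal single-band raster container with text (ESRI ASCII grid) I/O.

Grids are north-up in a projected CRS with coordinates in meters.  Pixel
membership follows a half-open convention: pixel (row i, col j) covers
``[x0 + j*s, x0 + (j+1)*s)`` in easting and ``(ytop - (i+1)*s, ytop - i*s]``
in northing, i.e. closed on the left/top edge, open on the right/bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band float raster.

    Parameters
    ----------
    values : 2-D array, row 0 = northernmost row (north-up).
    x0 : easting of the left (west) edge, m.
    y_top : northing of the top (north) edge, m.
    pixel_size : cell edge length, m.
    nodata : sentinel for missing cells.
    """

    values: np.ndarray
    x0: float = 0.0
    y_top: float | None = None
    pixel_size: float = 30.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.y_top is None:
            # default: y origin at 0 along the bottom edge
            self.y_top = self.values.shape[0] * self.pixel_size

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.x0,
            self.y_top - self.n_rows * self.pixel_size,
            self.x0 + self.n_cols * self.pixel_size,
            self.y_top,
        )

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 1e4

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the pixel containing (x, y) under the half-open rule."""
        col = int(np.floor((x - self.x0) / self.pixel_size))
        row = int(np.floor((self.y_top - y) / self.pixel_size))
        # the top edge itself belongs to row 0, not row -1
        if y == self.y_top:
            row = 0
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({x}, {y}) falls outside the raster extent")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.index_of(x, y)
        return float(self.values[r, c])

    def is_nodata(self, v: float) -> bool:
        return bool(np.isclose(v, self.nodata) or np.isnan(v))

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened arrays (x, y) of all pixel centers, row-major."""
        s = self.pixel_size
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * s
        ys = self.y_top - (np.arange(self.n_rows) + 0.5) * s
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()

    def copy_with(self, values: np.ndarray) -> "Raster":
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch")
        return Raster(
            np.asarray(values, dtype=float),
            x0=self.x0,
            y_top=self.y_top,
            pixel_size=self.pixel_size,
            nodata=self.nodata,
        )


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc), the text interchange raster format."""
    path = Path(path)
    ymin = raster.y_top - raster.n_rows * raster.pixel_size
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.x0:.6f}\n"
        f"yllcorner {ymin:.6f}\n"
        f"cellsize {raster.pixel_size:.6f}\n"
        f"NODATA_value {raster.nodata:.6f}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    values = values.reshape(n_rows, n_cols)
    size = header["cellsize"]
    return Raster(
        values,
        x0=header["xllcorner"],
        y_top=header["yllcorner"] + n_rows * size,
        pixel_size=size,
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )
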