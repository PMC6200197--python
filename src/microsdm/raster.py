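"""Single aligned raster grid type and ESRI ASCII grid I/O.

One :class:`RasterGrid` type carries every layer in the pipeline — DEM,
slope, aspect, TPI, microtopography classes, kriged factors, probability
and suitability maps — so alignment is checked once and everywhere.

Conventions
-----------
* Local planar coordinates in metres; no geodetic transforms.
* ``(x_origin, y_origin)`` is the **outer corner of the upper-left cell**
  (min-x, max-y of the covered extent); row 0 is the northernmost row.
* A cell's value refers to its centre:
  ``x = x_origin + (col + 0.5) * cell_size``,
  ``y = y_origin - (row + 0.5) * cell_size``.
* Nodata is ``NaN`` in the float value array.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, FormatError

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A rectangular grid of cell-centre values in a local metric frame."""

    x_origin: float
    y_origin: float
    cell_size: float
    values: np.ndarray  # 2-D float array, NaN = nodata

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    # -- basic geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return ~np.isnan(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def x_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, each shaped like values."""
        X, Y = np.meshgrid(self.x_centers(), self.y_centers())
        return X, Y

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing planar point (x, y)."""
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_origin - y) / self.cell_size))
        return row, col

    # -- alignment ------------------------------------------------------
    def aligned_with(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def require_alignment(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"{what} grids are not aligned: "
                f"{self.shape}@({self.x_origin},{self.y_origin},{self.cell_size}) vs "
                f"{other.shape}@({other.x_origin},{other.y_origin},{other.cell_size})"
            )

    # -- construction helpers -------------------------------------------
    def like(self, values: np.ndarray) -> "RasterGrid":
        """A new grid on the same georeference carrying ``values``."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise AlignmentError(
                f"replacement values shape {values.shape} != grid shape {self.shape}"
            )
        return RasterGrid(self.x_origin, self.y_origin, self.cell_size, values)

    def full_like(self, fill: float = np.nan) -> "RasterGrid":
        return self.like(np.full(self.shape, fill, dtype=float))

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.x_origin, self.y_origin, self.cell_size, self.values.copy())

    # -- convenience ----------------------------------------------------
    def plot(self, ax=None, title: str | None = None, cmap: str = "viridis", **kwargs):
        """Quick-look map of the layer (matplotlib imshow in metric extent)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        extent = [
            self.x_origin,
            self.x_origin + self.n_cols * self.cell_size,
            self.y_origin - self.n_rows * self.cell_size,
            self.y_origin,
        ]
        im = ax.imshow(self.values, extent=extent, cmap=cmap, **kwargs)
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        if title:
            ax.set_title(title)
        plt.colorbar(im, ax=ax)
        return ax


def write_ascii_grid(grid: RasterGrid, path, nodata: float = DEFAULT_NODATA,
                     precision: int = 10) -> None:
    """Write a grid as an ESRI ASCII raster (.asc)."""
    vals = np.where(grid.mask, grid.values, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {(grid.y_origin - grid.n_rows * grid.cell_size)!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    buf = io.StringIO()
    buf.write(header)
    np.savetxt(buf, vals, fmt=f"%.{precision}g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII raster into a :class:`RasterGrid`."""
    header: dict[str, float] = {}
    required = ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize"]
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in required + ["nodata_value"]:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    missing = [k for k in required if k not in header]
    if missing:
        raise FormatError(f"ASCII grid header missing {missing}")
    body = np.loadtxt(io.StringIO("".join(lines[i:])), ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (nrows, ncols):
        raise FormatError(
            f"ASCII grid body shape {body.shape} inconsistent with header "
            f"({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.where(body == nodata, np.nan, body)
    cell = header["cellsize"]
    return RasterGrid(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        values=values,
    )
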