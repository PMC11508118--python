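"""Gridded raster data model and neighborhood/transform primitives.

A :class:`RasterGrid` is a plain 2-D array of floats with a square cell
size in meters, a boolean nodata mask and an (informational) origin.  It
carries every surface in the scoring pipeline: elevation, flow
accumulation, convexity and the final inundation score.  Grids are
assumed to be already projected (UTM or similar) so that horizontal
distances are in meters; row 0 is the northern edge and indices are
0-based ``(row, col)``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import ndimage


class RasterError(ValueError):
    """Invalid raster construction or operation argument."""


class EmptyGridError(RasterError):
    """Every cell of the input grid is nodata."""


class DegenerateRangeError(RasterError):
    """Normalization requested on a constant (zero-range) grid."""


class RasterGrid:
    """2-D grid of real values with cell size, nodata mask and origin.

    Parameters
    ----------
    values
        2-D float array.  Units depend on role (m for elevation,
        dimensionless for scores).
    cell_size
        Side length of a (square) cell in meters; must be > 0.
    nodata_mask
        Boolean array, same shape as ``values``; True marks cells that
        are excluded from every statistic and filter window.  Defaults
        to all-False.
    origin
        ``(x, y)`` of the outer corner of cell (0, 0), informational.
    """

    def __init__(self, values, cell_size=1.0, nodata_mask=None, origin=(0.0, 0.0)):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise RasterError(f"values must be a non-empty 2-D grid, got shape {values.shape}")
        if not (cell_size > 0):
            raise RasterError(f"cell_size must be > 0, got {cell_size}")
        if nodata_mask is None:
            nodata_mask = np.zeros(values.shape, dtype=bool)
        else:
            nodata_mask = np.asarray(nodata_mask, dtype=bool)
            if nodata_mask.shape != values.shape:
                raise RasterError(
                    f"nodata_mask shape {nodata_mask.shape} != values shape {values.shape}"
                )
        self.values = values
        self.cell_size = float(cell_size)
        self.nodata_mask = nodata_mask
        self.origin = (float(origin[0]), float(origin[1]))

    # -- conveniences -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "RasterGrid":
        """New grid sharing geometry but with different cell values."""
        return RasterGrid(
            values,
            cell_size=self.cell_size,
            nodata_mask=self.nodata_mask.copy() if nodata_mask is None else nodata_mask,
            origin=self.origin,
        )

    def require_nonempty(self) -> None:
        if self.n_valid == 0:
            raise EmptyGridError("grid has no valid (non-nodata) cells")


def focal_mean(grid: RasterGrid, window: int, edge: str = "shrink") -> RasterGrid:
    """Moving-window (low-pass) mean filter.

    Each output cell is the arithmetic mean of the valid cells in the
    centered ``window x window`` neighborhood.  Nodata cells stay nodata
    and are omitted from their neighbors' means.

    Parameters
    ----------
    grid
        Input raster.
    window
        Odd positive window side length (cells).
    edge
        ``"shrink"`` (default): average only the in-bounds part of the
        window near edges, matching common GIS focal statistics.
        ``"reflect"``: mirror the grid across its edges first.
    """
    if not isinstance(window, (int, np.integer)) or window < 1 or window % 2 == 0:
        raise RasterError(f"window must be an odd positive integer, got {window!r}")
    grid.require_nonempty()
    if edge not in ("shrink", "reflect"):
        raise RasterError(f"unknown edge policy {edge!r}")
    if window == 1:
        return grid.with_values(grid.values.copy())

    valid = grid.valid_mask.astype(float)
    vals = np.where(grid.valid_mask, grid.values, 0.0)
    mode = "constant" if edge == "shrink" else "mirror"
    # Sum of valid values / count of valid cells within the window.
    ssum = ndimage.uniform_filter(vals, size=window, mode=mode) * window**2
    cnt = ndimage.uniform_filter(valid, size=window, mode=mode) * window**2
    cnt = np.round(cnt) if edge == "shrink" else cnt
    with np.errstate(invalid="ignore", divide="ignore"):
        out = ssum / cnt
    out[grid.nodata_mask] = np.nan
    # Isolated valid cells fully surrounded by nodata keep their value.
    lonely = grid.valid_mask & ~(cnt > 0)
    out[lonely] = grid.values[lonely]
    return grid.with_values(out)


def log_transform(grid: RasterGrid, base: float = 10.0) -> RasterGrid:
    """Map each valid cell ``x -> log(x + 1)`` (log10 by default).

    The +1 offset sends zero accumulation to zero score; the transform
    is strictly monotone so cell ranking is preserved.
    """
    grid.require_nonempty()
    vals = grid.values
    neg = grid.valid_mask & (vals < 0)
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise RasterError(f"log_transform requires nonnegative cells; cell ({r}, {c}) = {vals[r, c]}")
    out = np.where(grid.valid_mask, np.log1p(np.where(grid.valid_mask, vals, 0.0)), np.nan)
    out = out / np.log(base)
    return grid.with_values(out)


def normalize_01(grid: RasterGrid) -> RasterGrid:
    """Affinely rescale valid cells so min -> 0 and max -> 1.

    The normalization is over the full analysis extent, so per-site
    values depend on the extent of the raster supplied.
    """
    grid.require_nonempty()
    v = grid.valid_values()
    lo, hi = float(v.min()), float(v.max())
    if not hi > lo:
        raise DegenerateRangeError(f"cannot normalize constant grid (all valid cells = {lo})")
    out = np.where(grid.valid_mask, (grid.values - lo) / (hi - lo), np.nan)
    return grid.with_values(out)


# ---------------------------------------------------------------------
# Raster I/O: ESRI ASCII grid (text, carries cell size and nodata) and
# single-band float TIFF (cell size supplied by caller).
# ---------------------------------------------------------------------

_ASCII_NODATA = -9999.0


def write_ascii_grid(grid: RasterGrid, path: str | Path, nodata_value: float = _ASCII_NODATA) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    rows, cols = grid.shape
    vals = np.where(grid.nodata_mask, nodata_value, grid.values)
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {grid.origin[0]}\n"
        f"yllcorner {grid.origin[1]}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {nodata_value}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc), honoring its NODATA value."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        vals = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterError(f"ASCII grid {path} missing header field {key}")
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise RasterError(
            f"ASCII grid {path}: data shape {vals.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value")
    mask = np.isclose(vals, nodata) if nodata is not None else np.zeros(vals.shape, bool)
    mask |= np.isnan(vals)
    return RasterGrid(
        vals,
        cell_size=header["cellsize"],
        nodata_mask=mask,
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


def write_tiff(grid: RasterGrid, path: str | Path) -> None:
    """Write a single-band float32 TIFF (nodata stored as NaN)."""
    import tifffile

    vals = np.where(grid.nodata_mask, np.nan, grid.values).astype(np.float32)
    tifffile.imwrite(path, vals)


def read_tiff(path: str | Path, cell_size: float = 1.0) -> RasterGrid:
    """Read a single-band float TIFF; NaN cells become nodata."""
    import tifffile

    vals = np.asarray(tifffile.imread(path), dtype=float)
    if vals.ndim != 2:
        raise RasterError(f"TIFF {path} is not single-band 2-D (shape {vals.shape})")
    return RasterGrid(vals, cell_size=cell_size, nodata_mask=np.isnan(vals))


def read_raster(path: str | Path, cell_size: float = 1.0) -> RasterGrid:
    """Dispatch on extension: .asc/.txt -> ASCII grid, .tif/.tiff -> TIFF."""
    suffix = Path(path).suffix.lower()
    if suffix in (".asc", ".txt"):
        return read_ascii_grid(path)
    if suffix in (".tif", ".tiff"):
        return read_tiff(path, cell_size=cell_size)
    raise RasterError(f"unrecognized raster extension {suffix!r} for {path}")


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    suffix = Path(path).suffix.lower()
    if suffix in (".asc", ".txt"):
        write_ascii_grid(grid, path)
    elif suffix in (".tif", ".tiff"):
        write_tiff(grid, path)
    else:
        raise RasterError(f"unrecognized raster extension {suffix!r} for {path}")
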