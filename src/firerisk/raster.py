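"""Grid/layer data model and raster I/O shared by the whole pipeline.

Conventions
-----------
Rasters are row-major with the origin at the *outer corner of the top-left
cell*; cell ``(row, col)`` (0-based) has its center at
``origin + ((col + 0.5) * cell_size, -(row + 0.5) * cell_size)``.
Cell size is in kilometres (the working resolution of the analysis is 1 km).
Nodata propagates: any operation touching a masked cell yields a masked cell.

Two on-disk formats are supported: ESRI ASCII grid and GeoTIFF.  GeoTIFF
files are written through :mod:`tifffile` with the standard georeferencing
tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA) so they open in any GIS.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "Grid",
    "Layer",
    "Stack",
    "GridMismatchError",
    "RasterFormatError",
    "read_raster",
    "write_raster",
    "aggregate_fraction",
]

ASCII_NODATA = -9999.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridMismatchError(ValueError):
    """Raised when layers with incompatible grids are combined."""


class RasterFormatError(ValueError):
    """Raised when a raster file has an inconsistent or unsupported header."""


@dataclass(frozen=True)
class Grid:
    """Geometry of a raster: shape, cell size (km), origin and nodata mask.

    The mask marks cells outside the study region (True = nodata); it is
    shared by every layer on the grid.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None  # True where nodata

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        m = self.mask
        if m is None:
            m = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        else:
            m = np.asarray(m, dtype=bool)
            if m.shape != (self.n_rows, self.n_cols):
                raise ValueError("mask shape must match grid dimensions")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2

    @property
    def n_valid(self) -> int:
        return int((~self.mask).sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each of shape (rows, cols)."""
        ox, oy = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = ox + (cols + 0.5) * self.cell_size
        y = oy - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)[0], np.meshgrid(x, y)[1]

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def compatible(self, other: "Grid") -> bool:
        return self.same_geometry(other) and bool(np.array_equal(self.mask, other.mask))


@dataclass
class Layer:
    """One gridded variable: continuous values or non-negative integer codes."""

    grid: Grid
    name: str
    values: np.ndarray
    kind: str = "continuous"  # "continuous" | "categorical"
    codes: tuple[int, ...] | None = None  # declared codes for categorical layers
    units: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.shape != self.grid.shape:
            raise GridMismatchError(
                f"layer {self.name!r}: values shape {v.shape} != grid {self.grid.shape}"
            )
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "categorical":
            v = v.astype(np.int64)
            valid = v[~self.grid.mask]
            if valid.size and valid.min() < 0:
                raise ValueError("categorical codes must be non-negative")
            if self.codes is None:
                self.codes = tuple(int(c) for c in np.unique(valid))
            else:
                unknown = set(np.unique(valid)) - set(self.codes)
                if unknown:
                    raise ValueError(f"undeclared categorical codes: {sorted(unknown)}")
        else:
            v = v.astype(np.float64)
            if not np.all(np.isfinite(v[~self.grid.mask])):
                raise ValueError(f"layer {self.name!r}: non-finite values on unmasked cells")
        self.values = v

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[~self.grid.mask]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Layer":
        return Layer(
            grid=self.grid,
            name=name or self.name,
            values=values,
            kind=self.kind,
            codes=self.codes,
            units=self.units,
        )


@dataclass
class Stack:
    """Ordered collection of layers sharing one grid, addressable by name."""

    layers: list[Layer] = field(default_factory=list)

    def __post_init__(self):
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names in stack")
        for l in self.layers[1:]:
            if not l.grid.compatible(self.layers[0].grid):
                raise GridMismatchError(f"layer {l.name!r} on a mismatched grid")

    @property
    def grid(self) -> Grid:
        if not self.layers:
            raise ValueError("empty stack has no grid")
        return self.layers[0].grid

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __getitem__(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)

    def add(self, layer: Layer) -> None:
        if layer.name in self:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        if self.layers and not layer.grid.compatible(self.grid):
            raise GridMismatchError(f"layer {layer.name!r} on a mismatched grid")
        self.layers.append(layer)

    def replace(self, layer: Layer) -> "Stack":
        """Return a new stack with the named layer swapped; self unchanged."""
        if layer.name not in self:
            raise KeyError(layer.name)
        if not layer.grid.compatible(self.grid):
            raise GridMismatchError(f"replacement {layer.name!r} on a mismatched grid")
        return Stack([layer if l.name == layer.name else l for l in self.layers])


# ---------------------------------------------------------------------------
# I/O


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".asc", ".txt"):
        return "ascii_grid"
    if ext in (".tif", ".tiff"):
        return "geotiff"
    raise RasterFormatError(f"cannot infer raster format from {path!r}")


def read_raster(path: str, fmt: str | None = None, name: str | None = None,
                kind: str = "continuous") -> Layer:
    """Read a raster file into a :class:`Layer`.

    Grid metadata comes from the file header; cells equal to the nodata
    sentinel become masked.
    """
    fmt = _infer_format(path, fmt)
    if not os.path.exists(path):
        raise IOError(f"no such raster: {path}")
    if fmt == "ascii_grid":
        grid, values = _read_ascii(path)
    elif fmt == "geotiff":
        grid, values = _read_geotiff(path)
    else:
        raise RasterFormatError(f"unknown format {fmt!r}")
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    return Layer(grid=grid, name=name, values=values, kind=kind)


def write_raster(layer: Layer, path: str, fmt: str | None = None) -> None:
    """Write a layer to disk; re-reading reproduces values, mask and grid."""
    fmt = _infer_format(path, fmt)
    if fmt == "ascii_grid":
        _write_ascii(layer, path)
    elif fmt == "geotiff":
        _write_geotiff(layer, path)
    else:
        raise RasterFormatError(f"unknown format {fmt!r}")


def _read_ascii(path: str) -> tuple[Grid, np.ndarray]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        try:
            values = np.loadtxt(fh, dtype=np.float64, ndmin=2)
        except ValueError as exc:
            raise RasterFormatError(f"unparseable ASCII grid body in {path}: {exc}")
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"ASCII grid {path} missing header field {key!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise RasterFormatError(
            f"ASCII grid {path}: body shape {values.shape} != header ({n_rows}, {n_cols})"
        )
    nodata = header.get("nodata_value", ASCII_NODATA)
    mask = values == nodata
    cell = header["cellsize"]
    # header stores the lower-left corner; our origin is the upper-left corner
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    origin = (xll, yll + n_rows * cell)
    grid = Grid(n_rows, n_cols, cell_size=cell, origin=origin, mask=mask)
    values = values.copy()
    values[mask] = 0.0
    return grid, values


def _write_ascii(layer: Layer, path: str) -> None:
    g = layer.grid
    xll = g.origin[0]
    yll = g.origin[1] - g.n_rows * g.cell_size
    vals = layer.values.astype(np.float64).copy()
    vals[g.mask] = ASCII_NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"nodata_value {ASCII_NODATA!r}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def _write_geotiff(layer: Layer, path: str) -> None:
    g = layer.grid
    if layer.kind == "categorical":
        nodata = -1
        vals = layer.values.astype(np.int32).copy()
        vals[g.mask] = nodata
    else:
        nodata = ASCII_NODATA
        vals = layer.values.astype(np.float64).copy()
        vals[g.mask] = nodata
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin[0], g.origin[1], 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def _read_geotiff(path: str) -> tuple[Grid, np.ndarray]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        try:
            sx, sy, _ = tags[_TAG_PIXEL_SCALE].value
            tie = tags[_TAG_TIEPOINT].value
        except KeyError:
            raise RasterFormatError(f"GeoTIFF {path} lacks georeferencing tags")
        if not np.isclose(sx, sy):
            raise RasterFormatError(f"GeoTIFF {path}: anisotropic pixels unsupported")
        origin = (float(tie[3]), float(tie[4]))
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else ASCII_NODATA
    values = np.atleast_2d(np.asarray(values))
    mask = values == nodata
    grid = Grid(values.shape[0], values.shape[1], cell_size=float(sx),
                origin=origin, mask=mask)
    values = values.astype(np.float64, copy=True)
    values[mask] = 0.0
    return grid, values


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_fraction(fine: Layer, factor: int) -> Layer:
    """Fraction of 1-cells per coarse block of a fine binary layer.

    Each ``factor x factor`` block of the fine grid collapses to one coarse
    cell holding the fraction of its fine cells equal to 1.  The global mean
    over fully valid blocks is conserved exactly.  A coarse cell with any
    masked constituent is masked (nodata propagates).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    g = fine.grid
    if g.n_rows % factor or g.n_cols % factor:
        raise GridMismatchError(
            f"fine grid {g.shape} not divisible by factor {factor}"
        )
    vals = np.asarray(fine.values, dtype=np.float64)
    uniq = np.unique(vals[~g.mask])
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("aggregate_fraction expects a binary {0,1} layer")
    nr, nc = g.n_rows // factor, g.n_cols // factor
    blocks = vals.reshape(nr, factor, nc, factor)
    frac = blocks.mean(axis=(1, 3))
    coarse_mask = g.mask.reshape(nr, factor, nc, factor).any(axis=(1, 3))
    frac[coarse_mask] = 0.0
    coarse = Grid(nr, nc, cell_size=g.cell_size * factor, origin=g.origin,
                  mask=coarse_mask)
    return Layer(grid=coarse, name=fine.name, values=frac, kind="continuous")
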