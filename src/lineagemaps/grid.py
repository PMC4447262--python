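"""Raster and point-occurrence data model.

A :class:`Grid` is the universal raster currency of the package: a 2-D
array of cell values (habitat suitability in ``[0, 1]`` or a derived
quantity) with minimal georeferencing — the map coordinates of the outer
corner of the top-left cell, a square cell size, and a nodata mask.
Rasters are read and written as single-band GeoTIFF (via :mod:`tifffile`,
using the standard GeoTIFF ModelPixelScale / ModelTiepoint / GDAL_NODATA
tags) or as ESRI ASCII grids.

Coordinates are treated as planar: distances downstream use ``cell_size``
as opaque map units without latitude correction.  Users working on
geographic grids should either accept that distortion or supply projected
rasters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Grid",
    "GridStack",
    "OccurrenceTable",
    "read_grid",
    "write_grid",
    "read_occurrences",
    "snap_to_cells",
    "aggregate_sum",
]

_GEOTIFF_SUFFIXES = {".tif", ".tiff", ".gtiff"}
_ASCII_SUFFIXES = {".asc", ".agr", ".grd", ".txt"}

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_DEFAULT_NODATA = -9999.0


@dataclass
class Grid:
    """A single-band raster with square cells.

    Parameters
    ----------
    values
        2-D float array of cell values.  Masked cells may hold any value;
        they are ignored by every operation.
    origin_x, origin_y
        Map coordinates of the *outer* corner of the top-left cell
        (``origin_y`` is the top edge; rows increase downward, y decreases).
    cell_size
        Positive edge length of a cell in map units.  Cells are square.
    nodata_mask
        Boolean array, same shape as ``values``; True marks nodata cells.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape must match values shape")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def same_geometry(self, other: "Grid", rtol: float = 1e-9) -> bool:
        """True if *other* shares shape, origin and cell size with self."""
        return (
            self.shape == other.shape
            and np.isclose(self.origin_x, other.origin_x, rtol=rtol, atol=1e-9)
            and np.isclose(self.origin_y, other.origin_y, rtol=rtol, atol=1e-9)
            and np.isclose(self.cell_size, other.cell_size, rtol=rtol)
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the centre of cell ``(row, col)``."""
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def copy(self, values: np.ndarray | None = None) -> "Grid":
        """A deep copy, optionally substituting a new value array."""
        return Grid(
            values=np.array(self.values if values is None else values, dtype=float),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            nodata_mask=self.nodata_mask.copy(),
        )

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=self.nodata_mask)

    def check_suitability(self) -> None:
        """Raise if any unmasked value falls outside ``[0, 1]``."""
        vals = self.values[~self.nodata_mask]
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError(
                "suitability values must lie in [0, 1]; "
                f"found range [{np.nanmin(vals)}, {np.nanmax(vals)}]"
            )


@dataclass
class GridStack:
    """An ordered stack of geometrically identical grids with slice ages.

    Slices are ordered most-recent-first; ``ages_ka`` (thousands of years
    before present, present = 0) must be strictly increasing.
    """

    grids: list[Grid]
    ages_ka: list[float]

    def __post_init__(self) -> None:
        if len(self.grids) != len(self.ages_ka):
            raise ValueError("grids and ages_ka must have equal length")
        if len(self.grids) == 0:
            raise ValueError("GridStack must contain at least one slice")
        ages = np.asarray(self.ages_ka, dtype=float)
        if np.any(ages < 0):
            raise ValueError("ages must be non-negative (ka before present)")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages_ka must be strictly increasing (most recent first)")
        ref = self.grids[0]
        for g in self.grids[1:]:
            if not ref.same_geometry(g):
                raise ValueError("all grids in a GridStack must share geometry")

    def __len__(self) -> int:
        return len(self.grids)

    def __iter__(self):
        return iter(self.grids)

    def as_array(self) -> np.ndarray:
        """Stack values into a (n_slices, rows, cols) array."""
        return np.stack([g.values for g in self.grids])

    def union_mask(self) -> np.ndarray:
        """Cells masked in any slice."""
        m = np.zeros(self.grids[0].shape, dtype=bool)
        for g in self.grids:
            m |= g.nodata_mask
        return m


@dataclass
class OccurrenceTable:
    """Point records ``(species, lineage, x, y)``.

    A blank (empty-string) lineage marks an unsequenced, species-only
    record; sequenced specimens carry the lineage label of their clade.
    """

    data: pd.DataFrame = field(default_factory=lambda: _empty_occurrence_frame())

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = {"species", "lineage", "x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
        df["species"] = df["species"].astype(str)
        df["lineage"] = df["lineage"].fillna("").astype(str)
        df["x"] = pd.to_numeric(df["x"])
        df["y"] = pd.to_numeric(df["y"])
        if (df["species"].str.len() == 0).any():
            raise ValueError("every record needs a non-empty species name")
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise ValueError("occurrence coordinates must be finite")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float, float]]
    ) -> "OccurrenceTable":
        df = pd.DataFrame(list(records), columns=["species", "lineage", "x", "y"])
        return cls(df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def for_species(self, species: str) -> "OccurrenceTable":
        return OccurrenceTable(self.data[self.data["species"] == species])

    def sequenced(self) -> "OccurrenceTable":
        return OccurrenceTable(self.data[self.data["lineage"] != ""])

    def unsequenced(self) -> "OccurrenceTable":
        return OccurrenceTable(self.data[self.data["lineage"] == ""])

    def lineages_of(self, species: str) -> list[str]:
        sub = self.data[(self.data["species"] == species) & (self.data["lineage"] != "")]
        return sorted(sub["lineage"].unique())

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def _empty_occurrence_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {"species": pd.Series(dtype=str), "lineage": pd.Series(dtype=str),
         "x": pd.Series(dtype=float), "y": pd.Series(dtype=float)}
    )


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"geotiff", "ascii_grid"}:
            raise ValueError(f"unknown raster format: {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in _GEOTIFF_SUFFIXES:
        return "geotiff"
    if suffix in _ASCII_SUFFIXES:
        return "ascii_grid"
    raise ValueError(
        f"cannot infer raster format from suffix {suffix!r}; pass format="
    )


def read_grid(
    path: str | Path,
    format: str | None = None,
    suitability: bool = False,
) -> Grid:
    """Read a single-band raster into a :class:`Grid`.

    Parameters
    ----------
    path
        File to read.
    format
        ``"geotiff"`` or ``"ascii_grid"``; inferred from the suffix when
        omitted.
    suitability
        If True, reject unmasked values outside ``[0, 1]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    grid = _read_geotiff(path) if fmt == "geotiff" else _read_ascii(path)
    if suitability:
        grid.check_suitability()
    return grid


def write_grid(grid: Grid, path: str | Path, format: str | None = None) -> None:
    """Write a :class:`Grid`, encoding masked cells as the format's nodata."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        _write_ascii(grid, path)


def _read_geotiff(path: Path) -> Grid:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = np.asarray(page.asarray(), dtype=float)
        if values.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster")
        tags = page.tags
        if _TAG_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
            if not np.isclose(sx, sy, rtol=1e-9):
                raise ValueError(f"{path}: non-square cells ({sx} x {sy}) rejected")
            cell_size = float(sx)
        else:
            cell_size = 1.0
        if _TAG_TIEPOINT in tags:
            tie = tags[_TAG_TIEPOINT].value
            # tiepoint maps raster (i, j) -> map (x, y); we require the
            # conventional (0, 0) anchor at the outer top-left corner
            origin_x = float(tie[3]) - float(tie[0]) * cell_size
            origin_y = float(tie[4]) + float(tie[1]) * cell_size
        else:
            origin_x, origin_y = 0.0, 0.0
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            try:
                nodata = float(tags[_TAG_GDAL_NODATA].value)
            except (TypeError, ValueError):
                nodata = None
    mask = np.zeros(values.shape, dtype=bool)
    if nodata is not None:
        mask = np.isclose(values, nodata) | np.isnan(values)
    else:
        mask = np.isnan(values)
    if not cell_size > 0:
        raise ValueError(f"{path}: cell size must be positive")
    return Grid(values, origin_x, origin_y, cell_size, mask)


def _write_geotiff(grid: Grid, path: Path) -> None:
    out = grid.values.astype(np.float64).copy()
    out[grid.nodata_mask] = _DEFAULT_NODATA
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(_DEFAULT_NODATA)),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            data_start = i
            break
    else:
        data_start = len(lines)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ASCII grid header missing {key}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell_size = header["cellsize"]
    if not cell_size > 0:
        raise ValueError(f"{path}: cellsize must be positive, got {cell_size}")
    values = np.loadtxt(lines[data_start:], ndmin=2, dtype=float)
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    if "xllcorner" in header:
        origin_x = header["xllcorner"]
    elif "xllcenter" in header:
        origin_x = header["xllcenter"] - cell_size / 2
    else:
        raise ValueError(f"{path}: header missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cell_size / 2
    else:
        raise ValueError(f"{path}: header missing yllcorner/yllcenter")
    origin_y = yll + nrows * cell_size
    nodata = header.get("nodata_value")
    mask = np.isnan(values)
    if nodata is not None:
        mask |= np.isclose(values, nodata)
    return Grid(values, origin_x, origin_y, cell_size, mask)


def _write_ascii(grid: Grid, path: Path) -> None:
    nrows, ncols = grid.shape
    yll = grid.origin_y - nrows * grid.cell_size
    out = grid.values.copy()
    out[grid.nodata_mask] = _DEFAULT_NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {_DEFAULT_NODATA}\n")
        np.savetxt(fh, out, fmt="%.10g")


# ---------------------------------------------------------------------------
# Occurrence I/O and snapping
# ---------------------------------------------------------------------------


def read_occurrences(path: str | Path, strict: bool = False) -> OccurrenceTable:
    """Read an occurrence CSV with columns ``species,lineage,x,y``.

    Rows with non-numeric coordinates are dropped with a warning, or raise
    under ``strict=True``.  A blank lineage marks an unsequenced record.
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"species": str, "lineage": str}, keep_default_na=False
    )
    missing = {"species", "lineage", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    bad = x.isna() | y.isna() | ~np.isfinite(x.fillna(np.inf)) | ~np.isfinite(y.fillna(np.inf))
    if bad.any():
        if strict:
            raise ValueError(
                f"{path}: {int(bad.sum())} row(s) with non-numeric coordinates"
            )
        warnings.warn(
            f"{path}: dropping {int(bad.sum())} row(s) with bad coordinates",
            stacklevel=2,
        )
        df = df[~bad]
        x, y = x[~bad], y[~bad]
    df = df.assign(x=x.astype(float), y=y.astype(float))
    return OccurrenceTable(df)


def snap_to_cells(
    table: OccurrenceTable, grid: Grid
) -> tuple[list[tuple[int, int, int]], list[int]]:
    """Map each record to the raster cell containing it.

    Cells are half-open intervals ``[edge, edge + cell_size)`` on each
    axis (for y, the numerically lower edge belongs to the cell), so
    boundary points are assigned deterministically.

    Returns
    -------
    in_extent
        List of ``(record_index, row, col)``.
    out_of_extent
        Record indices falling outside the raster extent.  Nothing is
        silently dropped: every record appears in exactly one list.
    """
    xs = table.data["x"].to_numpy(dtype=float)
    ys = table.data["y"].to_numpy(dtype=float)
    tx = (xs - grid.origin_x) / grid.cell_size
    ty = (grid.origin_y - ys) / grid.cell_size
    cols = np.floor(tx).astype(int)
    rows = (np.ceil(ty) - 1).astype(int)
    ok = (cols >= 0) & (cols < grid.n_cols) & (rows >= 0) & (rows < grid.n_rows)
    in_extent = [(int(i), int(rows[i]), int(cols[i])) for i in np.flatnonzero(ok)]
    out = [int(i) for i in np.flatnonzero(~ok)]
    return in_extent, out


def aggregate_sum(grid: Grid, factor: int) -> Grid:
    """Coarsen a grid by summing ``factor x factor`` blocks.

    Masked cells contribute zero; a block that is entirely masked stays
    masked.  Ragged edge blocks are summed over the cells available.  The
    total of unmasked values is conserved for every factor.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return grid.copy()
    nrows, ncols = grid.shape
    out_r = -(-nrows // factor)
    out_c = -(-ncols // factor)
    vals = np.where(grid.nodata_mask, 0.0, grid.values)
    padded = np.zeros((out_r * factor, out_c * factor))
    padded[:nrows, :ncols] = vals
    summed = padded.reshape(out_r, factor, out_c, factor).sum(axis=(1, 3))
    unmasked = np.zeros((out_r * factor, out_c * factor), dtype=bool)
    unmasked[:nrows, :ncols] = ~grid.nodata_mask
    count = unmasked.reshape(out_r, factor, out_c, factor).sum(axis=(1, 3))
    return Grid(
        values=summed,
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        cell_size=grid.cell_size * factor,
        nodata_mask=count == 0,
    )
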