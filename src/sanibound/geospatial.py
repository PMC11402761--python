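"""Gridding and mapping: IDW interpolation, boundary rasters, classes.

Transmissivity and well depth are interpolated from point wells onto a
regular metric grid (inverse distance weighting, default power 2 over
the 12 nearest neighbours, 50 m cells), the boundary equation is
evaluated per cell, and the resulting map is cut into k equal-width
ranges (R1..R5 in the published map).  Rasters are written as ESRI
ASCII grids.

Coordinates: well tables carry lon/lat in decimal degrees and are
projected to metres either through the built-in UTM transform (crs
like ``"utm32n"``) or passed through unchanged for synthetic fields
already in a local metric frame (crs ``"local"``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _utm
from .boundary import BoundaryModel, eval_boundary
from .well_data import WellDataError, WellTable

__all__ = [
    "RasterGrid",
    "ClassifiedRaster",
    "project_wells",
    "idw_interpolate",
    "grid_from_bounds",
    "rasterize_field",
    "boundary_raster",
    "classify_equal_interval",
    "write_ascii_grid",
    "read_ascii_grid",
    "raster_summary",
]

log = logging.getLogger(__name__)

_COINCIDENT = 1e-9  # metres: a target this close to a sample is an exact hit


@dataclass
class RasterGrid:
    """A north-up regular grid in projected metric coordinates.

    ``values`` is (nrows, ncols) with row 0 the northernmost row; NaN
    marks nodata internally, serialized as ``nodata`` in ASCII output.
    ``x_origin``/``y_origin`` are the lower-left corner.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    nodata: float = -9999.0
    crs: str = "local"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise WellDataError("raster values must be 2-D")
        if not self.cell_size > 0:
            raise WellDataError(f"cell size must be > 0, got {self.cell_size}")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) arrays of cell-centre coordinates, row-major north-up."""
        xs = self.x_origin + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.y_origin + (np.arange(self.nrows)[::-1] + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size, other.cell_size)
        )


@dataclass
class ClassifiedRaster:
    """Class-index raster (1..k) with exact edges and display ranges."""

    grid: RasterGrid            # values are class indices (float, NaN nodata)
    edges: np.ndarray           # length k+1, strictly increasing, exact
    labels: tuple[str, ...]     # ("R1", ..., "Rk")
    display_ranges: tuple[tuple[int, int], ...]

    def histogram(self) -> dict[str, int]:
        v = self.grid.values
        return {
            lab: int(np.sum(v == i + 1)) for i, lab in enumerate(self.labels)
        }


def project_wells(wells: WellTable, crs: str = "utm32n") -> WellTable:
    """Append metric ``x_m``/``y_m`` columns.

    ``crs`` is ``"local"`` (coordinates already metres; existing
    ``x_m``/``y_m`` pass through, otherwise lon/lat are taken as
    metres) or ``"utm<zone><n|s>"`` for the built-in WGS84 UTM
    transform.  Geographic CRSs cannot be used for gridding.
    """
    out = wells.copy()
    if crs == "local":
        if "x_m" not in out.frame.columns:
            out.frame["x_m"] = out.frame["lon"].astype(float)
            out.frame["y_m"] = out.frame["lat"].astype(float)
        return out
    m = re.fullmatch(r"utm(\d{1,2})([ns])", crs.lower())
    if not m:
        raise WellDataError(
            f"unsupported CRS {crs!r}: use 'local' or 'utm<zone><n|s>' "
            "(geographic CRSs are not metric and cannot grid)"
        )
    zone, south = int(m.group(1)), m.group(2) == "s"
    x, y = _utm.geographic_to_utm(
        out.frame["lon"].to_numpy(float), out.frame["lat"].to_numpy(float),
        zone, south,
    )
    out.frame["x_m"] = x
    out.frame["y_m"] = y
    return out


def _check_duplicates(xy: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge duplicate sample locations with equal values; conflicting ones error."""
    order = np.lexsort(xy.T)
    keep = np.ones(len(xy), dtype=bool)
    for a, b in zip(order[:-1], order[1:]):
        if np.hypot(*(xy[a] - xy[b])) < _COINCIDENT:
            if not np.isclose(values[a], values[b]):
                raise WellDataError(
                    f"duplicate sample location {tuple(xy[a])} with "
                    f"conflicting values {values[a]} and {values[b]}"
                )
            keep[b] = False
    return xy[keep], values[keep]


def idw_interpolate(
    samples_xy,
    sample_values,
    targets_xy,
    power: float = 2.0,
    n_neighbors: int | None = 12,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation at target points.

    value = sum(w_i v_i) / sum(w_i) with w_i = d_i^(-power), over the
    ``n_neighbors`` nearest samples (all samples when None).  A target
    within 1e-9 m of a sample returns that sample's value exactly.
    """
    xy = np.atleast_2d(np.asarray(samples_xy, dtype=float))
    vals = np.asarray(sample_values, dtype=float)
    tg = np.atleast_2d(np.asarray(targets_xy, dtype=float))
    if len(xy) == 0:
        raise WellDataError("idw_interpolate: no samples")
    if not power > 0:
        raise WellDataError(f"IDW power must be > 0, got {power}")
    xy, vals = _check_duplicates(xy, vals)
    k = len(xy) if n_neighbors is None else min(n_neighbors, len(xy))
    tree = cKDTree(xy)
    d, idx = tree.query(tg, k=k)
    d = np.atleast_2d(d.reshape(len(tg), k))
    idx = np.atleast_2d(idx.reshape(len(tg), k))
    out = np.empty(len(tg))
    exact = d[:, 0] < _COINCIDENT
    out[exact] = vals[idx[exact, 0]]
    rest = ~exact
    if rest.any():
        w = d[rest] ** (-power)
        out[rest] = np.sum(w * vals[idx[rest]], axis=1) / np.sum(w, axis=1)
    return out


def grid_from_bounds(
    xmin: float, ymin: float, xmax: float, ymax: float,
    cell_size: float = 50.0, crs: str = "local", nodata: float = -9999.0,
) -> RasterGrid:
    """An all-nodata grid whose cells cover the given bounding box."""
    if not (xmax > xmin and ymax > ymin):
        raise WellDataError("empty bounding box")
    ncols = int(np.ceil((xmax - xmin) / cell_size))
    nrows = int(np.ceil((ymax - ymin) / cell_size))
    return RasterGrid(
        np.full((nrows, ncols), np.nan), xmin, ymin, cell_size, nodata, crs
    )


def rasterize_field(
    wells: WellTable,
    fieldname: str,
    grid: RasterGrid,
    power: float = 2.0,
    n_neighbors: int | None = 12,
    max_radius: float | None = None,
) -> RasterGrid:
    """IDW-interpolate one well attribute onto every cell centre.

    Cells farther than ``max_radius`` from the nearest sample are
    nodata (default: no radius, all cells filled).  Requires >= 3 wells
    with the field and projected x_m/y_m coordinates, and a grid that
    covers at least one well.
    """
    wells.require_columns(["x_m", "y_m", fieldname])
    sub = wells.frame[["x_m", "y_m", fieldname]].dropna()
    if len(sub) == 0:
        raise WellDataError(f"no wells carry {fieldname!r}")
    if len(sub) < 3:
        log.warning("rasterize_field: only %d well(s) with %r; the surface "
                    "is poorly constrained", len(sub), fieldname)
    xy = sub[["x_m", "y_m"]].to_numpy(float)
    xmax = grid.x_origin + grid.ncols * grid.cell_size
    ymax = grid.y_origin + grid.nrows * grid.cell_size
    inside = (
        (xy[:, 0] >= grid.x_origin) & (xy[:, 0] <= xmax)
        & (xy[:, 1] >= grid.y_origin) & (xy[:, 1] <= ymax)
    )
    if not inside.any():
        raise WellDataError("grid does not cover any well")
    gx, gy = grid.cell_centers()
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    vals = idw_interpolate(xy, sub[fieldname].to_numpy(float), targets,
                           power, n_neighbors)
    if max_radius is not None:
        d, _ = cKDTree(xy).query(targets, k=1)
        vals[d > max_radius] = np.nan
    out = RasterGrid(vals.reshape(grid.nrows, grid.ncols), grid.x_origin,
                     grid.y_origin, grid.cell_size, grid.nodata, grid.crs)
    return out


def boundary_raster(
    model: BoundaryModel, tr_raster: RasterGrid, depth_raster: RasterGrid
) -> RasterGrid:
    """Apply the boundary equation cell-wise; nodata propagates."""
    if not tr_raster.aligned_with(depth_raster):
        raise WellDataError(
            "misaligned rasters: "
            f"tr(origin=({tr_raster.x_origin}, {tr_raster.y_origin}), "
            f"cell={tr_raster.cell_size}, shape={tr_raster.values.shape}) vs "
            f"depth(origin=({depth_raster.x_origin}, {depth_raster.y_origin}), "
            f"cell={depth_raster.cell_size}, shape={depth_raster.values.shape})"
        )
    tr = tr_raster.values
    dp = depth_raster.values
    out = np.full_like(tr, np.nan)
    ok = ~(np.isnan(tr) | np.isnan(dp))
    out[ok] = eval_boundary(model, tr[ok], dp[ok])
    return RasterGrid(out, tr_raster.x_origin, tr_raster.y_origin,
                      tr_raster.cell_size, tr_raster.nodata, tr_raster.crs)


def classify_equal_interval(raster: RasterGrid, k: int = 5,
                            labels: tuple[str, ...] | None = None) -> ClassifiedRaster:
    """Cut a raster into k equal-width classes spanning [min, max].

    Intervals are left-closed/right-open except the last (closed).
    Display ranges round the exact real edges to integers so that
    consecutive ranges abut at consecutive integers, mirroring the
    published R1..R5 style (e.g. 39-105, 106-171, ...).  A constant
    raster yields a single class with a warning.
    """
    if k < 2:
        raise WellDataError(f"need k >= 2 classes, got {k}")
    v = raster.values
    finite = v[~np.isnan(v)]
    if finite.size == 0:
        raise WellDataError("cannot classify an all-nodata raster")
    vmin, vmax = float(finite.min()), float(finite.max())
    if vmin == vmax:
        log.warning("classify_equal_interval: constant raster; single class")
        cls = np.where(np.isnan(v), np.nan, 1.0)
        edges = np.array([vmin, vmax])
        disp = ((int(np.floor(vmin + 0.5)), int(np.floor(vmax + 0.5))),)
        return ClassifiedRaster(
            RasterGrid(cls, raster.x_origin, raster.y_origin, raster.cell_size,
                       raster.nodata, raster.crs),
            edges, ("R1",), disp,
        )
    edges = np.linspace(vmin, vmax, k + 1)
    cls = np.full_like(v, np.nan)
    ok = ~np.isnan(v)
    idx = np.digitize(v[ok], edges[1:-1], right=False) + 1  # 1..k
    cls[ok] = idx
    # display: round edges half-away-from-zero; lower bound of class i+1
    # is the (rounded) upper bound of class i plus one.
    rounded = [int(np.floor(e + 0.5)) for e in edges]
    disp = []
    lo = rounded[0]
    for i in range(k):
        hi = rounded[i + 1]
        disp.append((lo, hi))
        lo = hi + 1
    if labels is None:
        labels = tuple(f"R{i + 1}" for i in range(k))
    return ClassifiedRaster(
        RasterGrid(cls, raster.x_origin, raster.y_origin, raster.cell_size,
                   raster.nodata, raster.crs),
        edges, labels, tuple(disp),
    )


def write_ascii_grid(raster: RasterGrid, path, fmt: str = "%.6f") -> None:
    """Write an ESRI ASCII grid (north-up, row-major)."""
    v = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.x_origin:.6f}\n")
        fh.write(f"yllcorner {raster.y_origin:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:g}\n")
        for row in v:
            fh.write(" ".join(fmt % x for x in row) + "\n")


def read_ascii_grid(path, crs: str = "local") -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    with open(path, "r", encoding="utf-8") as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    nodata = header["nodata_value"]
    values[values == nodata] = np.nan
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise WellDataError("ASCII grid data does not match its header")
    return RasterGrid(values, header["xllcorner"], header["yllcorner"],
                      header["cellsize"], nodata, crs)


def raster_summary(raster: RasterGrid) -> dict[str, float]:
    """min/max/mean over non-nodata cells (errors if all nodata)."""
    v = raster.values[~np.isnan(raster.values)]
    if v.size == 0:
        raise WellDataError("raster_summary: all cells are nodata")
    return {
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "n_cells": int(v.size),
    }
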