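"""Periodic 2D grids over the membrane plane.

All map-producing analyses share :class:`GridMap`: a scalar field sampled on a
regular Nx x Ny grid spanning the (periodic) simulation box in x and y.  Cell
(i, j) covers ``[i*cx, (i+1)*cx) x [j*cy, (j+1)*cy)``; values live at cell
centres.  Cells never visited by any particle carry NaN and zero occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention.

    ``delta`` has shape (..., d) and ``box`` holds the d edge lengths of an
    orthorhombic box.
    """
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def wrap_positions(xy: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Fold coordinates into the primary box [0, L) per axis."""
    box = np.asarray(box, dtype=float)
    out = np.mod(xy, box)
    # float round-off can map -eps to exactly L, which must fold to 0
    return np.where(out >= box, 0.0, out)


@dataclass
class GridMap:
    """Periodic scalar field over the membrane plane.

    Attributes
    ----------
    values : (Nx, Ny) float array; NaN in zero-occupancy cells.
    occupancy : (Nx, Ny) sample counts per cell.
    cell_size : edge length of a (square) grid cell, nm.
    box : (Lx, Ly) lateral box edges, nm.
    units : unit string of ``values``.
    extrapolated : boolean mask of cells whose value was filled by smoothing
        from data further than 3 sigma away (unreliable).
    """

    values: np.ndarray
    occupancy: np.ndarray
    cell_size: float
    box: tuple[float, float]
    units: str = ""
    periodic: bool = True
    extrapolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.occupancy = np.asarray(self.occupancy)
        if self.values.shape != self.occupancy.shape:
            raise ValueError("values and occupancy shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.shape
        cx = self.box[0] / nx
        cy = self.box[1] / ny
        return (np.arange(nx) + 0.5) * cx, (np.arange(ny) + 0.5) * cy

    def cell_of(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Indices of the cells containing lateral positions ``xy`` (..., 2)."""
        xy = wrap_positions(np.asarray(xy, dtype=float), np.asarray(self.box))
        nx, ny = self.shape
        ix = np.minimum((xy[..., 0] / self.box[0] * nx).astype(int), nx - 1)
        iy = np.minimum((xy[..., 1] / self.box[1] * ny).astype(int), ny - 1)
        return ix, iy

    def value_at(self, xy: np.ndarray) -> np.ndarray:
        ix, iy = self.cell_of(xy)
        return self.values[ix, iy]

    def copy_with(self, **kwargs) -> "GridMap":
        return replace(self, **kwargs)


def grid_shape(box: tuple[float, float], cell: float) -> tuple[int, int]:
    if cell <= 0:
        raise ValueError("grid cell size must be positive")
    nx = max(1, int(round(box[0] / cell)))
    ny = max(1, int(round(box[1] / cell)))
    return nx, ny


def accumulate(
    xy: np.ndarray,
    weights: np.ndarray,
    box: tuple[float, float],
    cell: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin weighted samples onto the grid; returns (sum, count) arrays."""
    nx, ny = grid_shape(box, cell)
    xy = wrap_positions(np.asarray(xy, dtype=float), np.asarray(box))
    ix = np.minimum((xy[:, 0] / box[0] * nx).astype(int), nx - 1)
    iy = np.minimum((xy[:, 1] / box[1] * ny).astype(int), ny - 1)
    flat = ix * ny + iy
    sums = np.bincount(flat, weights=np.asarray(weights, dtype=float), minlength=nx * ny)
    cnts = np.bincount(flat, minlength=nx * ny)
    return sums.reshape(nx, ny), cnts.reshape(nx, ny)


def mean_map(
    xy: np.ndarray,
    values: np.ndarray,
    box: tuple[float, float],
    cell: float,
    units: str = "",
    smoothing_sigma: float = 0.0,
) -> GridMap:
    """Per-cell mean of point samples, optionally with periodic Gaussian smoothing.

    Smoothing uses occupancy-weighted (normalized) convolution so empty cells
    are filled from nearby data; filled cells further than 3 sigma from any
    datum are flagged ``extrapolated``.
    """
    sums, cnts = accumulate(xy, values, box, cell)
    if smoothing_sigma > 0:
        sig_cells = smoothing_sigma / cell
        ssum = ndimage.gaussian_filter(sums, sig_cells, mode="wrap")
        scnt = ndimage.gaussian_filter(cnts.astype(float), sig_cells, mode="wrap")
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(scnt > 1e-12, ssum / np.maximum(scnt, 1e-300), np.nan)
        extrap = _far_from_data(cnts > 0, box, cell, 3.0 * smoothing_sigma)
        vals[extrap & np.isnan(vals)] = np.nan
        occ = cnts
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        extrap = np.zeros_like(vals, dtype=bool)
        occ = cnts
    return GridMap(vals, occ, cell, (float(box[0]), float(box[1])), units=units,
                   extrapolated=extrap)


def _far_from_data(occupied: np.ndarray, box, cell: float, radius: float) -> np.ndarray:
    """Cells whose periodic distance to the nearest occupied cell exceeds radius."""
    if occupied.all() or not occupied.any():
        return np.zeros_like(occupied, dtype=bool)
    nx, ny = occupied.shape
    cx, cy = box[0] / nx, box[1] / ny
    xs = (np.arange(nx) + 0.5) * cx
    ys = (np.arange(ny) + 0.5) * cy
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts_occ = np.column_stack([gx[occupied], gy[occupied]])
    pts_all = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(pts_occ, boxsize=(box[0], box[1]))
    d, _ = tree.query(np.mod(pts_all, (box[0], box[1])))
    return (d.reshape(nx, ny) > radius) & ~occupied


def periodic_point_distance(p: np.ndarray, q: np.ndarray, box) -> np.ndarray:
    """Minimum-image Euclidean distance between lateral points."""
    d = minimum_image(np.asarray(p, dtype=float) - np.asarray(q, dtype=float),
                      np.asarray(box, dtype=float))
    return np.sqrt((d ** 2).sum(axis=-1))


def cyclic_shift(gm: GridMap, sx: int, sy: int) -> GridMap:
    """Shift a map by whole cells with periodic wrap (testing aid)."""
    return gm.copy_with(
        values=np.roll(gm.values, (sx, sy), axis=(0, 1)),
        occupancy=np.roll(gm.occupancy, (sx, sy), axis=(0, 1)),
        extrapolated=None if gm.extrapolated is None
        else np.roll(gm.extrapolated, (sx, sy), axis=(0, 1)),
    )
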