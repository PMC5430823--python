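"""Gridded maps over the membrane plane and interleaflet order correlation.

All maps are periodic in x and y, time-averaged over the analysis window by
default, and share :class:`~memnano.grids.GridMap`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import grids
from .grids import GridMap, accumulate, grid_shape, mean_map
from .leaflets import SamplingError, unwrap_trace
from .model import (
    GeometryError,
    LeafletAssignment,
    Topology,
    Trajectory,
    reference_points,
)
from .order import PerChainOrder

DEFAULT_CELL = 0.5  # nm; resolves a ~10 nm domain with ~20 cells across
DEFAULT_SIGMA = 1.0  # nm Gaussian smoothing for surface/thickness maps


@dataclass
class JointOrderHistogram:
    """Joint distribution of co-located upper/lower local chain order."""

    hist: np.ndarray  # (nb, nb), sums to 1
    bin_edges: np.ndarray
    pearson_r: float
    diagonal_band_mass: float
    band_width: float

    def __post_init__(self) -> None:
        if not np.isclose(self.hist.sum(), 1.0, atol=1e-9):
            raise ValueError("joint histogram must be normalized")


def surface_map(
    traj: Trajectory,
    top: Topology,
    assignment: LeafletAssignment,
    leaflet: str,
    grid_cell: float = DEFAULT_CELL,
    smoothing_sigma: float = DEFAULT_SIGMA,
) -> GridMap:
    """Time-averaged phosphorus height (nm) of one leaflet, smoothed periodically."""
    if grid_cell <= 0:
        raise ValueError("grid_cell must be positive")
    box2 = (traj.box[0], traj.box[1])
    mols = [k for k in assignment.molecules_in(leaflet)
            if top.molecules[k].species == "DPPC"]
    if not mols:
        raise GeometryError(f"no DPPC in {leaflet} leaflet")
    heads = [top.molecules[k].head for k in mols]
    xy, z = [], []
    for fr in traj.frames:
        p = fr.positions[heads]
        xy.append(p[:, :2])
        z.append(p[:, 2])
    return mean_map(np.concatenate(xy), np.concatenate(z), box2, grid_cell,
                    units="nm", smoothing_sigma=smoothing_sigma)


def thickness_map(
    traj: Trajectory,
    top: Topology,
    assignment: LeafletAssignment,
    grid_cell: float = DEFAULT_CELL,
    smoothing_sigma: float = DEFAULT_SIGMA,
) -> GridMap:
    """Phosphate-to-phosphate membrane thickness per cell (nm)."""
    up = surface_map(traj, top, assignment, "upper", grid_cell, smoothing_sigma)
    lo = surface_map(traj, top, assignment, "lower", grid_cell, smoothing_sigma)
    return GridMap(up.values - lo.values, up.occupancy + lo.occupancy,
                   grid_cell, up.box, units="nm",
                   extrapolated=None if up.extrapolated is None
                   else up.extrapolated | lo.extrapolated)


def order_map(
    pco: PerChainOrder,
    traj: Trajectory,
    top: Topology,
    assignment: LeafletAssignment,
    leaflet: str,
    grid_cell: float = DEFAULT_CELL,
) -> GridMap:
    """Per-cell mean chain-mean order of the leaflet's DPPC, time-averaged.

    Each molecule contributes its window-averaged scalar order at its
    reference-point position in every frame; cells no molecule ever visits
    are NaN with zero occupancy.
    """
    box2 = (traj.box[0], traj.box[1])
    ids, mol_order = pco.molecule_means()
    order_of = dict(zip(ids.tolist(), mol_order))
    sel = [k for k in assignment.molecules_in(leaflet)
           if top.molecules[k].id in order_of]
    if not sel:
        raise ValueError(f"no molecules with computed order in {leaflet} leaflet")
    vals = np.array([order_of[top.molecules[k].id] for k in sel])
    nx, ny = grid_shape(box2, grid_cell)
    sums = np.zeros((nx, ny))
    cnts = np.zeros((nx, ny), dtype=int)
    for fr in traj.frames:
        refs = reference_points(top, fr.positions)[sel]
        s, c = accumulate(refs[:, :2], vals, box2, grid_cell)
        sums += s
        cnts += c
    with np.errstate(invalid="ignore"):
        mv = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return GridMap(mv, cnts, grid_cell, box2, units="-S_CD")


def jump_map(
    traj: Trajectory,
    top: Topology,
    assignment: LeafletAssignment,
    leaflet: str,
    window: float = 1.0,
    grid_cell: float = DEFAULT_CELL,
) -> GridMap:
    """Mean in-plane displacement (nm) per fixed time window, binned at the
    window's start position.  Low values mark immobile, gel-like regions."""
    if traj.dt is None or traj.dt <= 0:
        raise SamplingError("trajectory has no usable frame spacing")
    k = int(round(window / traj.dt))
    if k < 1 or abs(k * traj.dt - window) > 1e-6 + 1e-3 * traj.dt:
        raise SamplingError(
            f"window {window} ns is shorter than or not a multiple of the frame spacing"
        )
    if traj.n_frames <= k:
        raise SamplingError("trajectory shorter than one displacement window")
    box2 = (traj.box[0], traj.box[1])
    sel = list(assignment.molecules_in(leaflet))
    refs = np.stack([reference_points(top, fr.positions)[sel] for fr in traj.frames])
    refs = unwrap_trace(traj, refs)
    nx, ny = grid_shape(box2, grid_cell)
    sums = np.zeros((nx, ny))
    cnts = np.zeros((nx, ny), dtype=int)
    for start in range(0, traj.n_frames - k, k):
        d = refs[start + k, :, :2] - refs[start, :, :2]
        disp = np.hypot(d[:, 0], d[:, 1])
        s, c = accumulate(refs[start, :, :2], disp, box2, grid_cell)
        sums += s
        cnts += c
    with np.errstate(invalid="ignore"):
        mv = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return GridMap(mv, cnts, grid_cell, box2, units="nm")


def interleaflet_histogram(
    order_upper: GridMap,
    order_lower: GridMap,
    bins: np.ndarray | int = 20,
    band_width: float = 0.05,
) -> JointOrderHistogram:
    """Joint histogram of co-located upper/lower cell order + Pearson r.

    The diagonal-band mass is the joint probability of |upper - lower| <=
    ``band_width``; near 1 for a registered membrane.
    """
    if order_upper.shape != order_lower.shape or not np.allclose(
        order_upper.box, order_lower.box
    ):
        raise ValueError("order maps must share the same grid")
    u = order_upper.values.ravel()
    l = order_lower.values.ravel()
    ok = np.isfinite(u) & np.isfinite(l)
    if ok.sum() < 2:
        raise ValueError("too few jointly occupied cells")
    u, l = u[ok], l[ok]
    if np.isscalar(bins):
        lo = min(u.min(), l.min())
        hi = max(u.max(), l.max())
        pad = 0.05 * (hi - lo + 1e-12)
        edges = np.linspace(lo - pad, hi + pad, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    h, _, _ = np.histogram2d(u, l, bins=[edges, edges])
    h /= h.sum()
    r = float(np.corrcoef(u, l)[0, 1])
    band = float(np.mean(np.abs(u - l) <= band_width))
    return JointOrderHistogram(h, edges, r, band, band_width)


def area_per_lipid(
    frame_box: tuple[float, float, float],
    top: Topology,
    assignment: LeafletAssignment,
    leaflet: str,
    count_cholesterol: bool = True,
) -> float:
    """Lateral box area divided by the leaflet's lipid count (nm^2)."""
    mols = assignment.molecules_in(leaflet)
    n = 0
    for k in mols:
        m = top.molecules[k]
        if m.is_sterol and not count_cholesterol:
            continue
        n += 1
    if n == 0:
        raise GeometryError(f"{leaflet} leaflet contains no counted lipids")
    return float(frame_box[0] * frame_box[1] / n)
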