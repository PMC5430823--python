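"""Leaflet assignment and in-plane displacement.

Leaflets are assigned against the *local* bilayer midplane: the per-cell mean
of the upper and lower phosphate surfaces.  A rippled (undulating) membrane is
therefore handled correctly — a sterol below the global mean height but above
the local midplane still belongs to the upper leaflet.
"""

from __future__ import annotations

import numpy as np

from . import grids
from .grids import GridMap, mean_map, minimum_image
from .model import (
    GeometryError,
    LeafletAssignment,
    Topology,
    Trajectory,
    reference_points,
)


class SamplingError(ValueError):
    """Requested interval is not representable on the frame grid."""


def assign_leaflets(
    traj: Trajectory,
    top: Topology,
    grid_cell: float = 0.5,
    smoothing_sigma: float = 1.0,
) -> LeafletAssignment:
    """Label every lipid upper/lower per frame and return the midplane surface.

    DPPC is assigned by phosphorus height relative to the local midplane,
    sterols by ring-centroid height.  The midplane is the per-cell mean of the
    two phosphorus surfaces, bootstrapped from a global mean-height split.
    """
    box2 = (traj.box[0], traj.box[1])
    dppc = [m for m in top.molecules if m.species == "DPPC"]
    if not dppc:
        raise GeometryError("no DPPC molecules to define the bilayer surfaces")

    # bootstrap: split phosphates about the per-frame global mean height
    head_xy, head_z, head_side = [], [], []
    for fr in traj.frames:
        z = np.array([fr.positions[m.head][2] for m in dppc])
        xy = np.array([fr.positions[m.head][:2] for m in dppc])
        mid = z.mean()
        head_xy.append(xy)
        head_z.append(z)
        head_side.append(np.where(z >= mid, 1, -1))
    head_xy = np.concatenate(head_xy)
    head_z = np.concatenate(head_z)
    head_side = np.concatenate(head_side)
    if not (head_side == 1).any() or not (head_side == -1).any():
        raise GeometryError("degenerate geometry: a leaflet has zero lipids")

    upper = mean_map(head_xy[head_side == 1], head_z[head_side == 1], box2,
                     grid_cell, units="nm", smoothing_sigma=smoothing_sigma)
    lower = mean_map(head_xy[head_side == -1], head_z[head_side == -1], box2,
                     grid_cell, units="nm", smoothing_sigma=smoothing_sigma)
    mid_vals = 0.5 * (upper.values + lower.values)
    # any cell still empty after smoothing falls back to the global midplane
    fallback = 0.5 * (np.nanmean(upper.values) + np.nanmean(lower.values))
    mid_vals = np.where(np.isfinite(mid_vals), mid_vals, fallback)
    midplane = GridMap(mid_vals, upper.occupancy + lower.occupancy, grid_cell,
                       box2, units="nm")

    labels = np.zeros((traj.n_frames, top.n_molecules), dtype=np.int8)
    for fi, fr in enumerate(traj.frames):
        refs = reference_points(top, fr.positions)
        local_mid = midplane.value_at(refs[:, :2])
        labels[fi] = np.where(refs[:, 2] >= local_mid, 1, -1)

    static = np.where(labels.sum(axis=0) >= 0, 1, -1).astype(np.int8)
    # DPPC leaflet identity is constant over the analysis window
    for k, m in enumerate(top.molecules):
        if m.species == "DPPC":
            labels[:, k] = static[k]
    if not (static == 1).any() or not (static == -1).any():
        raise GeometryError("degenerate geometry: a leaflet has zero lipids")
    return LeafletAssignment(labels=labels, static_labels=static, midplane=midplane)


def unwrap_trace(traj: Trajectory, points: np.ndarray) -> np.ndarray:
    """Remove periodic jumps from a (n_frames, ..., 2 or 3) lateral trace.

    Frame-to-frame steps are mapped to their minimum image and re-accumulated,
    so a molecule drifting across the box edge keeps its true path.  Only the
    lateral (x, y) components are unwrapped.
    """
    pts = np.array(points, dtype=float)
    box = np.asarray(traj.box[:2])
    lateral = pts[..., :2]
    steps = minimum_image(np.diff(lateral, axis=0), box)
    out = lateral.copy()
    out[1:] = lateral[0] + np.cumsum(steps, axis=0)
    pts[..., :2] = out
    return pts


def reference_trace(traj: Trajectory, top: Topology, mol_index: int,
                    unwrap: bool = True) -> np.ndarray:
    """(n_frames, 3) reference-point path of one molecule."""
    mol = top.molecules[mol_index]
    pts = np.empty((traj.n_frames, 3))
    for fi, fr in enumerate(traj.frames):
        if mol.is_sterol:
            pts[fi] = fr.positions[mol.ring].mean(axis=0)
        else:
            pts[fi] = fr.positions[mol.head]
    return unwrap_trace(traj, pts) if unwrap else pts


def lateral_displacement(traj: Trajectory, top: Topology, mol_index: int,
                         t0: float, dt: float) -> float:
    """|Δ(x, y)| of a molecule's reference point between t0 and t0 + dt (nm).

    Coordinates are unwrapped first, so a 0.2 nm hop across the periodic
    boundary reports 0.2 nm, never Lx - 0.2.
    """
    if traj.dt and abs(dt / traj.dt - round(dt / traj.dt)) > 1e-6:
        raise SamplingError(f"dt={dt} ns is not a multiple of the frame spacing")
    i0 = traj.frame_index(t0)
    i1 = traj.frame_index(t0 + dt)
    path = reference_trace(traj, top, mol_index, unwrap=True)
    d = path[i1, :2] - path[i0, :2]
    return float(np.hypot(d[0], d[1]))
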