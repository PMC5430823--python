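"""Chain-packing analyses: neighbour statistics, hexagonal order, cholesterol
partitioning versus thickness, collective tilt and sterol face orientation.

Chain "sites" are lateral points, one per DPPC acyl chain (centroid of the
chain carbons projected to xy), optionally one per cholesterol (ring
centroid).  Six nearest neighbours at the first-shell cutoff diagnose
hexagonal, gel-like packing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .grids import GridMap, minimum_image, wrap_positions
from .model import (
    Frame,
    GeometryError,
    LeafletAssignment,
    Topology,
    TopologyError,
)


@dataclass
class NeighborHistogram:
    counts: np.ndarray  # index = number of neighbours (0..max)
    cutoff: float
    include_cholesterol: bool
    per_site: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    @property
    def mode(self) -> int:
        return int(np.argmax(self.counts))


@dataclass
class ThicknessOccupancy:
    bin_edges: np.ndarray
    all_cells: np.ndarray  # normalized histogram over all cells
    cholesterol_cells: np.ndarray  # normalized; empty flag if no sterols
    cumulative_all: np.ndarray
    cumulative_chol: np.ndarray
    has_cholesterol: bool
    ks_statistic: float | None = None
    ks_pvalue: float | None = None


def chain_sites(
    frame: Frame,
    top: Topology,
    assignment: LeafletAssignment,
    leaflet: str,
    include_cholesterol: bool = False,
    frame_index: int = 0,
) -> np.ndarray:
    """(n_sites, 2) lateral chain sites of one leaflet in one frame."""
    want = 1 if leaflet == "upper" else -1
    pts = []
    for k, mol in enumerate(top.molecules):
        if assignment.labels[frame_index, k] != want:
            continue
        if mol.species == "DPPC":
            for ch in mol.chains:
                pts.append(frame.positions[ch.carbons].mean(axis=0)[:2])
        elif mol.is_sterol and include_cholesterol:
            pts.append(frame.positions[mol.ring].mean(axis=0)[:2])
    return np.array(pts) if pts else np.empty((0, 2))


def rdf_2d(
    sites: np.ndarray,
    box: tuple[float, float],
    dr: float = 0.02,
    r_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Periodic 2D radial distribution function of lateral sites.

    Returns (r centres, g(r), r of the first minimum after the first peak).
    The first minimum is the conventional first-coordination-shell cutoff.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    sites = np.asarray(sites, dtype=float)
    n = sites.shape[0]
    if n < 2:
        raise ValueError("need at least two sites")
    box = (float(box[0]), float(box[1]))
    if r_max is None:
        r_max = 0.5 * min(box)
    wrapped = wrap_positions(sites, np.asarray(box))
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    d = minimum_image(wrapped[pairs[:, 0]] - wrapped[pairs[:, 1]], np.asarray(box))
    dist = np.hypot(d[:, 0], d[:, 1])
    edges = np.arange(0.0, r_max + dr, dr)
    hist, _ = np.histogram(dist, bins=edges)
    area = box[0] * box[1]
    rho = n / area
    shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    # hist counts unordered pairs; ideal count per site-shell is rho*shell*n/2
    g = hist / (0.5 * n * rho * shell)
    centres = 0.5 * (edges[:-1] + edges[1:])
    rmin = _first_minimum(centres, g)
    return centres, g, rmin


def _first_minimum(r: np.ndarray, g: np.ndarray) -> float:
    """First local minimum of g(r) after its first peak (lightly smoothed)."""
    if g.size < 5:
        return float(r[-1])
    gs = np.convolve(g, np.ones(3) / 3.0, mode="same")
    ipk = None
    for i in range(1, gs.size - 1):
        if gs[i] > 1.0 and gs[i] >= gs[i - 1] and gs[i] >= gs[i + 1]:
            ipk = i
            break
    if ipk is None:
        ipk = int(np.argmax(gs))
    for i in range(ipk + 1, gs.size - 1):
        if gs[i] <= gs[i - 1] and gs[i] <= gs[i + 1]:
            return float(r[i])
    return float(r[min(ipk + 1, gs.size - 1)])


def neighbor_counts(
    sites: np.ndarray,
    box: tuple[float, float],
    cutoff: float,
    include_cholesterol: bool = False,
) -> NeighborHistogram:
    """Histogram of per-site neighbour numbers within a periodic cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sites = np.asarray(sites, dtype=float)
    box = (float(box[0]), float(box[1]))
    wrapped = wrap_positions(sites, np.asarray(box))
    tree = cKDTree(wrapped, boxsize=box)
    counts_per_site = np.array(
        [len(nb) - 1 for nb in tree.query_ball_point(wrapped, cutoff)]
    )
    nmax = max(12, counts_per_site.max(initial=0))
    hist = np.bincount(counts_per_site, minlength=nmax + 1)
    return NeighborHistogram(hist, cutoff, include_cholesterol, counts_per_site)


def thickness_occupancy(
    thickness: GridMap,
    sterol_xy_frames: list[np.ndarray],
    bin_width: float = 0.05,
) -> ThicknessOccupancy:
    """Thickness histogram over all cells versus cholesterol-occupied cells.

    A cell is "occupied" in a frame when it contains at least one sterol
    reference point; occupied-cell thickness values accumulate over frames.
    Includes a two-sample KS comparison of the two samples.
    """
    vals = thickness.values
    finite = np.isfinite(vals)
    all_vals = vals[finite]
    chol_vals = []
    for xy in sterol_xy_frames:
        if len(xy) == 0:
            continue
        ix, iy = thickness.cell_of(np.asarray(xy))
        occ = np.zeros_like(vals, dtype=bool)
        occ[ix, iy] = True
        chol_vals.append(vals[occ & finite])
    chol_vals = np.concatenate(chol_vals) if chol_vals else np.empty(0)

    lo = np.floor(all_vals.min() / bin_width) * bin_width
    hi = np.ceil(all_vals.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 1e-12, bin_width)
    h_all, _ = np.histogram(all_vals, bins=edges)
    h_all = h_all / h_all.sum()
    if chol_vals.size:
        h_ch, _ = np.histogram(chol_vals, bins=edges)
        h_ch = h_ch / h_ch.sum()
        ks = stats.ks_2samp(all_vals, chol_vals)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        h_ch = np.zeros(edges.size - 1)
        ks_stat = ks_p = None
    return ThicknessOccupancy(
        bin_edges=edges,
        all_cells=h_all,
        cholesterol_cells=h_ch,
        cumulative_all=np.cumsum(h_all),
        cumulative_chol=np.cumsum(h_ch),
        has_cholesterol=bool(chol_vals.size),
        ks_statistic=ks_stat,
        ks_pvalue=ks_p,
    )


def _chain_axis(chain_pos: np.ndarray) -> np.ndarray:
    """Unit chain axis from the first principal component of the carbons,
    oriented to have non-negative z (robust to gauche defects)."""
    centred = chain_pos - chain_pos.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def collective_tilt(
    frames: list[Frame],
    top: Topology,
    region_mask=None,
) -> tuple[float, float, np.ndarray]:
    """Mean chain tilt and degree of collective tilt within a region.

    ``region_mask(xy) -> bool`` selects chains by their lateral site; ``None``
    takes all DPPC chains.  Returns (mean tilt angle in degrees, mean
    resultant length of the lateral tilt directions in [0, 1], mean lateral
    direction vector).  A resultant near 0 means tilts are azimuthally
    uncorrelated — no collective tilting.
    """
    angles, dirs = [], []
    for fr in frames:
        for mol in top.by_species("DPPC"):
            for ch in mol.chains:
                cpos = fr.positions[ch.carbons]
                xy = cpos.mean(axis=0)[:2]
                if region_mask is not None and not region_mask(xy):
                    continue
                axis = _chain_axis(cpos)
                tilt = np.degrees(np.arccos(np.clip(axis[2], -1.0, 1.0)))
                angles.append(tilt)
                lat = axis[:2]
                norm = np.hypot(lat[0], lat[1])
                if norm > 1e-12:
                    dirs.append(lat / norm)
    if not angles:
        raise GeometryError("region contains no chains")
    mean_dir = np.mean(dirs, axis=0) if dirs else np.zeros(2)
    resultant = float(np.hypot(*mean_dir)) if dirs else 0.0
    return float(np.mean(angles)), resultant, mean_dir


def face_orientation_preference(
    frames: list[Frame],
    top: Topology,
    order_map: GridMap,
    sterol_indices: list[int] | None = None,
    gradient_tol: float = 1e-6,
) -> dict:
    """Do sterols point their rough (methyl-bearing) face toward disorder?

    For each sterol and frame, the lateral direction from the ring centroid to
    the methyl-marker atom defines the rough-face direction; minus the local
    gradient of the order map defines the toward-disordered direction.  The
    fraction of observations with a positive projection is tested against the
    0.5 null with a two-sided binomial test.  Sterols sitting where the order
    gradient vanishes (homogeneous membrane) are excluded; with no usable
    observations the report flags ``no_boundary``.
    """
    sterols = top.sterols()
    if sterol_indices is not None:
        sterols = [m for m in sterols if m.id in set(sterol_indices)]
    if not sterols:
        raise TopologyError("no sterols in topology")
    for m in sterols:
        if m.methyl_marker is None:
            raise TopologyError(f"sterol {m.id} lacks a methyl-side marker atom")

    gx, gy = _periodic_gradient(order_map)
    box = np.asarray(order_map.box)
    cosines = []
    toward_disorder = 0
    n_obs = 0
    for fr in frames:
        for m in sterols:
            centroid = fr.positions[m.ring].mean(axis=0)
            rough = fr.positions[m.methyl_marker][:2] - centroid[:2]
            rn = np.hypot(*rough)
            if rn < 1e-12:
                continue
            rough = rough / rn
            ix, iy = order_map.cell_of(centroid[:2])
            grad = np.array([gx[ix, iy], gy[ix, iy]])
            gn = np.hypot(*grad)
            if not np.isfinite(gn) or gn < gradient_tol:
                continue
            disorder_dir = -grad / gn
            c = float(rough @ disorder_dir)
            cosines.append(c)
            toward_disorder += c > 0
            n_obs += 1
    if n_obs == 0:
        return {"no_boundary": True, "n": 0}
    frac = toward_disorder / n_obs
    test = stats.binomtest(toward_disorder, n_obs, 0.5)
    return {
        "no_boundary": False,
        "n": n_obs,
        "fraction_toward_disordered": float(frac),
        "p_value": float(test.pvalue),
        "mean_cosine": float(np.mean(cosines)),
    }


def _periodic_gradient(gm: GridMap) -> tuple[np.ndarray, np.ndarray]:
    nx, ny = gm.shape
    cx, cy = gm.box[0] / nx, gm.box[1] / ny
    v = gm.values
    gx = (np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)) / (2 * cx)
    gy = (np.roll(v, -1, axis=1) - np.roll(v, 1, axis=1)) / (2 * cy)
    return gx, gy
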