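"""Region classification of the membrane plane and domain-area tracking.

Cells of a (smoothed, time-averaged) thickness map are labelled disordered /
ordered / core by two thresholds: thin disordered background, intermediate
ordered (liquid-ordered-like) domain, and the thickest hexagonally packed
core.  ``auto`` thresholds come from the crossing points of a 3-component 1D
Gaussian mixture fitted to the cell-value histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.mixture import GaussianMixture

from .grids import GridMap

CLASS_NAMES = {0: "disordered", 1: "ordered", 2: "core"}
UNLABELLED = -1  # NaN / never-occupied cells


@dataclass
class RegionMap:
    labels: np.ndarray  # (Nx, Ny) int: 0 disordered, 1 ordered, 2 core, -1 NaN
    thresholds: tuple[float, float]
    cell_size: float
    box: tuple[float, float]

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    def area(self, cls: int | str) -> float:
        if isinstance(cls, str):
            cls = {v: k for k, v in CLASS_NAMES.items()}[cls]
        return float((self.labels == cls).sum() * self.cell_area)

    @property
    def areas(self) -> dict[str, float]:
        return {name: self.area(k) for k, name in CLASS_NAMES.items()}

    @property
    def boundary(self) -> np.ndarray:
        """Cells with at least one differently labelled periodic 4-neighbour."""
        lb = self.labels
        diff = np.zeros_like(lb, dtype=bool)
        for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
            nb = np.roll(lb, sh, axis=ax)
            diff |= (nb != lb) & (lb != UNLABELLED) & (nb != UNLABELLED)
        return diff

    def boundary_cell_centres(self) -> np.ndarray:
        nx, ny = self.labels.shape
        cx, cy = self.box[0] / nx, self.box[1] / ny
        ii, jj = np.nonzero(self.boundary)
        return np.column_stack([(ii + 0.5) * cx, (jj + 0.5) * cy])


class ClassificationError(RuntimeError):
    """Automatic threshold selection failed; pass explicit thresholds."""


def _periodic_components(mask: np.ndarray) -> np.ndarray:
    """Connected components of a boolean grid, 4-connectivity, periodic wrap."""
    lab, n = ndimage.label(mask)
    if n == 0:
        return lab
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for a, b in zip(lab[0, :], lab[-1, :]):
        if a and b:
            union(a, b)
    for a, b in zip(lab[:, 0], lab[:, -1]):
        if a and b:
            union(a, b)
    out = lab.copy()
    for v in range(1, n + 1):
        out[lab == v] = find(v)
    return out


def _suppress_speckle(labels: np.ndarray, min_cells: int) -> np.ndarray:
    """Reassign connected class patches smaller than ``min_cells`` to the most
    common label among their periodic 4-neighbours."""
    out = labels.copy()
    changed = True
    guard = 0
    while changed and guard < 10:
        changed = False
        guard += 1
        for cls in np.unique(out):
            if cls == UNLABELLED:
                continue
            comp = _periodic_components(out == cls)
            for v in np.unique(comp):
                if v == 0:
                    continue
                patch = comp == v
                if patch.sum() >= min_cells:
                    continue
                neigh = []
                for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
                    nb = np.roll(out, sh, axis=ax)[patch]
                    neigh.extend(nb[nb != cls])
                neigh = [x for x in neigh if x != UNLABELLED]
                if neigh:
                    vals, cnts = np.unique(neigh, return_counts=True)
                    out[patch] = vals[np.argmax(cnts)]
                    changed = True
    return out


def auto_thresholds(values: np.ndarray, random_state: int = 0) -> tuple[float, float]:
    """Thresholds from the crossing points of a 3-component Gaussian mixture."""
    x = values[np.isfinite(values)].reshape(-1, 1)
    if x.size < 10:
        raise ClassificationError("too few cells for automatic thresholds")
    gm = GaussianMixture(3, n_init=5, random_state=random_state).fit(x)
    order = np.argsort(gm.means_.ravel())
    mu = gm.means_.ravel()[order]
    sd = np.sqrt(gm.covariances_.ravel()[order])
    w = gm.weights_[order]
    if np.any(np.diff(mu) < 1e-3):
        raise ClassificationError(
            "mixture fit did not resolve three thickness modes; "
            "supply explicit thresholds"
        )

    def crossing(i, j):
        grid = np.linspace(mu[i], mu[j], 2000)
        pi = w[i] * np.exp(-0.5 * ((grid - mu[i]) / sd[i]) ** 2) / sd[i]
        pj = w[j] * np.exp(-0.5 * ((grid - mu[j]) / sd[j]) ** 2) / sd[j]
        k = np.argmin(np.abs(pi - pj))
        return float(grid[k])

    return crossing(0, 1), crossing(1, 2)


def classify(
    thickness: GridMap,
    thresholds: tuple[float, float] | str = "auto",
    min_domain_cells: int = 4,
    random_state: int = 0,
) -> RegionMap:
    """Label cells disordered (< t1), ordered ([t1, t2)) or core (>= t2)."""
    if isinstance(thresholds, str):
        if thresholds != "auto":
            raise ValueError("thresholds must be (t1, t2) or 'auto'")
        t1, t2 = auto_thresholds(thickness.values, random_state)
    else:
        t1, t2 = thresholds
        if not t1 < t2:
            raise ValueError("thresholds must satisfy t1 < t2")
    v = thickness.values
    labels = np.full(v.shape, UNLABELLED, dtype=int)
    finite = np.isfinite(v)
    labels[finite & (v < t1)] = 0
    labels[finite & (v >= t1) & (v < t2)] = 1
    labels[finite & (v >= t2)] = 2
    if min_domain_cells > 1:
        labels = _suppress_speckle(labels, min_domain_cells)
    return RegionMap(labels, (float(t1), float(t2)), thickness.cell_size,
                     thickness.box)


def track_domain_area(
    thickness_maps: list[GridMap],
    thresholds: tuple[float, float] | str = "auto",
    min_domain_cells: int = 4,
) -> dict:
    """Per-window region areas and the final/initial ordered-domain area ratio.

    The tracked quantity is the combined (ordered + core) area — the
    footprint of the ordered nanodomain.
    """
    if len(thickness_maps) < 2:
        raise ValueError("need at least two windows to track domain area")
    if thresholds == "auto":
        # fit once on the first window so all windows share thresholds
        rm0 = classify(thickness_maps[0], "auto", min_domain_cells)
        thresholds = rm0.thresholds
    maps = [classify(tm, thresholds, min_domain_cells) for tm in thickness_maps]
    series = {name: np.array([m.area(name) for m in maps])
              for name in CLASS_NAMES.values()}
    domain = series["ordered"] + series["core"]
    ratio = float(domain[-1] / domain[0]) if domain[0] > 0 else float("nan")
    return {
        "areas": series,
        "domain_area": domain,
        "final_over_initial": ratio,
        "region_maps": maps,
    }


def boundary_distance(point_xy, region: RegionMap) -> float:
    """Minimum periodic distance (nm) from a point to any boundary-cell centre."""
    centres = region.boundary_cell_centres()
    if centres.shape[0] == 0:
        raise ValueError("region map has an empty boundary")
    tree = cKDTree(centres, boxsize=region.box)
    p = np.mod(np.asarray(point_xy, dtype=float), region.box)
    d, _ = tree.query(p)
    return float(d)


def boundary_distance_map(region: RegionMap) -> np.ndarray:
    """Periodic distance of every cell centre to the nearest boundary cell."""
    centres = region.boundary_cell_centres()
    if centres.shape[0] == 0:
        raise ValueError("region map has an empty boundary")
    nx, ny = region.labels.shape
    cx, cy = region.box[0] / nx, region.box[1] / ny
    xs = (np.arange(nx) + 0.5) * cx
    ys = (np.arange(ny) + 0.5) * cy
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(centres, boxsize=region.box)
    d, _ = tree.query(np.mod(pts, region.box))
    return d.reshape(nx, ny)
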