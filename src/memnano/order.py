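"""Deuterium order parameters.

The order parameter of a C-H bond is ``S_CD = <(3 cos^2 theta - 1)/2>`` with
``theta`` the angle between the bond and the membrane normal (z).  Following
NMR convention everything downstream reports ``-S_CD``, which is positive for
ordered chains and approaches 0.5 for a chain standing parallel to the normal
(its C-H bonds lie in the membrane plane).

Distributions are built from *per-chain time averages*: each chain contributes
one number per carbon (its -S_CD averaged over both hydrogens and all frames
of the window), and the histogram runs over chains.  This is what makes a
heterogeneous membrane show a multimodal distribution — gel-like, ordered and
disordered subpopulations each keep their identity over the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GeometryError, LeafletAssignment, Topology, TopologyError, Trajectory

#: default histogram grid over -S_CD: width 0.01 over [-0.1, 0.55] resolves
#: the gel / Lo / Ld modes without excessive noise.
DEFAULT_BINS = np.round(np.arange(-0.10, 0.55 + 1e-9, 0.01), 10)

#: default carbon range (sn numbering) entering the chain-mean scalar;
#: the terminal methyl is noisy and excluded.
DEFAULT_CARBON_RANGE = (2, 15)


@dataclass
class OrderProfile:
    """Mean -S_CD per carbon along a chain."""

    carbons: list[int]
    values: np.ndarray
    stderr: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"carbon": self.carbons, "mean_order": self.values})


@dataclass
class OrderDistribution:
    """Per-carbon normalized histograms of per-chain time-averaged -S_CD."""

    carbons: list[int]
    bin_edges: np.ndarray
    histograms: np.ndarray  # (n_carbons, n_bins), each row sums to 1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.histograms = np.asarray(self.histograms, dtype=float)
        sums = self.histograms.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-carbon histograms must be normalized")

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def same_binning(self, other: "OrderDistribution") -> bool:
        return (
            list(self.carbons) == list(other.carbons)
            and self.bin_edges.shape == other.bin_edges.shape
            and np.allclose(self.bin_edges, other.bin_edges)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, c in enumerate(self.carbons):
            for b, m in zip(self.bin_centres, self.histograms[ci]):
                rows.append((c, b, m))
        return pd.DataFrame(rows, columns=["carbon", "bin_centre", "mass"])

    def to_json(self, path) -> None:
        import json

        payload = {
            "carbons": list(map(int, self.carbons)),
            "bin_edges": self.bin_edges.tolist(),
            "histograms": self.histograms.tolist(),
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "OrderDistribution":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(d["carbons"], np.asarray(d["bin_edges"]),
                   np.asarray(d["histograms"]), d.get("provenance", {}))


@dataclass
class PerChainOrder:
    """Time-averaged -S_CD per (molecule, chain, carbon) over a window."""

    molecule_ids: np.ndarray  # (n_chains,)
    chain_labels: list[str]
    carbons: list[int]
    values: np.ndarray  # (n_chains, n_carbons)
    window: tuple[float, float]
    carbon_range: tuple[int, int] = DEFAULT_CARBON_RANGE

    def chain_means(self, carbon_range: tuple[int, int] | None = None) -> np.ndarray:
        """Scalar order per chain: mean over the configured carbon range."""
        lo, hi = carbon_range or self.carbon_range
        mask = [(lo <= c <= hi) for c in self.carbons]
        if not any(mask):
            raise ValueError("carbon range selects no carbons")
        return self.values[:, mask].mean(axis=1)

    def molecule_means(self, carbon_range: tuple[int, int] | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
        """(molecule ids, per-molecule mean over that molecule's chains)."""
        cm = self.chain_means(carbon_range)
        ids = np.unique(self.molecule_ids)
        means = np.array([cm[self.molecule_ids == i].mean() for i in ids])
        return ids, means


def scd_bond(c_pos: np.ndarray, h_pos: np.ndarray, normal=(0.0, 0.0, 1.0)) -> float:
    """S_CD of a single C-H bond instance: (3 cos^2 theta - 1)/2."""
    b = np.asarray(h_pos, dtype=float) - np.asarray(c_pos, dtype=float)
    n = np.asarray(normal, dtype=float)
    bb = np.dot(b, b)
    nn = np.dot(n, n)
    if bb == 0.0:
        raise GeometryError("zero-length C-H bond vector")
    if nn == 0.0:
        raise GeometryError("zero-length normal vector")
    c2 = np.dot(b, n) ** 2 / (bb * nn)
    return float(1.5 * c2 - 0.5)


def _reconstructed_ch_cos2(chain_pos: np.ndarray) -> np.ndarray:
    """cos^2(theta) of ideal C-H directions rebuilt from the carbon skeleton.

    For interior carbon i the two C-H bonds are perpendicular to the local
    C(i-1)->C(i+1) vector; with tetrahedral azimuthal symmetry their mean
    squared z-projection is (1 - u_z^2)/2 where u is the unit skeleton vector.
    Terminal carbons use the single adjacent bond.
    """
    n = chain_pos.shape[0]
    out = np.empty(n)
    for i in range(n):
        lo = max(i - 1, 0)
        hi = min(i + 1, n - 1)
        u = chain_pos[hi] - chain_pos[lo]
        norm = np.linalg.norm(u)
        if norm == 0:
            raise GeometryError("degenerate chain: coincident carbons")
        uz2 = (u[2] / norm) ** 2
        out[i] = (1.0 - uz2) / 2.0
    return out


def per_chain_order(
    traj: Trajectory,
    top: Topology,
    assignment: LeafletAssignment | None = None,
    chain: str | None = "sn-2",
    window: tuple[float, float] | None = None,
    species: str = "DPPC",
    reconstruct_hydrogens: bool = False,
    carbon_range: tuple[int, int] = DEFAULT_CARBON_RANGE,
) -> PerChainOrder:
    """Time-averaged -S_CD per chain carbon over the analysis window.

    The membrane normal is z.  Each carbon is averaged over all attached
    hydrogens and all frames; ``chain=None`` takes every chain of the species.
    Hydrogen-free topologies require ``reconstruct_hydrogens=True``.
    """
    times = traj.times
    if window is None:
        sel = np.arange(traj.n_frames)
        window = (float(times[0]), float(times[-1]))
    else:
        sel = np.where((times >= window[0] - 1e-9) & (times <= window[1] + 1e-9))[0]
        if sel.size == 0:
            raise ValueError("window selects no frames")

    chains = []
    for mol in top.by_species(species):
        for ch in mol.chains:
            if chain is None or ch.label == chain:
                chains.append((mol.id, ch))
    if not chains:
        raise ValueError(f"no {chain or 'any'} chains of species {species}")

    carbons = chains[0][1].carbon_numbers
    acc = np.zeros((len(chains), len(carbons)))
    box3 = np.asarray(traj.box)
    for fi in sel:
        pos = traj.frames[fi].positions
        for ci, (_mid, ch) in enumerate(chains):
            cpos = pos[ch.carbons]
            have_h = all(len(h) > 0 for h in ch.hydrogens)
            if have_h:
                for k, (c_idx, h_idx) in enumerate(zip(ch.carbons, ch.hydrogens)):
                    b = pos[h_idx] - pos[c_idx]
                    b -= box3 * np.round(b / box3)  # bonds never span half a box
                    c2 = (b[:, 2] ** 2) / (b ** 2).sum(axis=1)
                    acc[ci, k] += -np.mean(1.5 * c2 - 0.5)
            elif reconstruct_hydrogens:
                c2 = _reconstructed_ch_cos2(cpos)
                acc[ci] += -(1.5 * c2 - 0.5)
            else:
                raise TopologyError(
                    "chain carbons lack hydrogens and reconstruction is disabled"
                )
    acc /= sel.size
    return PerChainOrder(
        molecule_ids=np.array([mid for mid, _ in chains]),
        chain_labels=[ch.label for _, ch in chains],
        carbons=list(carbons),
        values=acc,
        window=window,
        carbon_range=carbon_range,
    )


def order_distribution(pco: PerChainOrder, bins: np.ndarray = DEFAULT_BINS,
                       provenance: dict | None = None) -> OrderDistribution:
    """Per-carbon normalized histograms over the per-chain time averages."""
    if pco.values.shape[0] == 0:
        raise ValueError("no chains in selection")
    bins = np.asarray(bins, dtype=float)
    hists = np.empty((len(pco.carbons), bins.size - 1))
    for k in range(len(pco.carbons)):
        h, _ = np.histogram(np.clip(pco.values[:, k], bins[0], bins[-1]), bins=bins)
        tot = h.sum()
        if tot == 0:
            raise ValueError("empty histogram — check bin range")
        hists[k] = h / tot
    return OrderDistribution(list(pco.carbons), bins, hists,
                             provenance=provenance or {"window_ns": pco.window})


def mean_profile(dist: OrderDistribution) -> OrderProfile:
    """Per-carbon expectation of -S_CD under the histogram."""
    centres = dist.bin_centres
    vals = dist.histograms @ centres
    return OrderProfile(list(dist.carbons), vals)
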