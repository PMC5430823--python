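"""Domain types shared by every analysis stage.

Coordinates are in nm throughout (GRO convention); times in ns.  Boxes are
orthorhombic — the analyses are plane-based and operate on the x/y face of the
box with the membrane normal along z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridMap

SPECIES = ("DPPC", "CHOL", "DMCHOL", "OTHER")
STEROLS = ("CHOL", "DMCHOL")


class StructureError(ValueError):
    """Inconsistent trajectory structure (e.g. atom count changes)."""


class TopologyError(ValueError):
    """Topology fails validation or lacks a required role."""


class GeometryError(ValueError):
    """Degenerate geometry (zero-length bond, empty leaflet, ...)."""


@dataclass
class Frame:
    """One time point: particle positions (N, 3) nm and an orthorhombic box."""

    time: float
    positions: np.ndarray
    box: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise StructureError("positions must have shape (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise StructureError("non-finite coordinates in frame")
        if any(b <= 0 for b in self.box):
            raise StructureError("box edges must be positive")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]


@dataclass
class ChainSpec:
    """One acyl chain: ordered carbon indices and the hydrogens bonded to each.

    ``carbons[k]`` is acyl carbon ``carbon_numbers[k]`` (sn numbering, C2 is
    the first carbon after the ester).  ``hydrogens[k]`` may be empty for
    united-atom input.
    """

    label: str  # "sn-1" | "sn-2"
    carbons: list[int]
    hydrogens: list[list[int]]
    carbon_numbers: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.hydrogens) != len(self.carbons):
            raise TopologyError("hydrogens list must parallel carbons list")
        if self.carbon_numbers is None:
            self.carbon_numbers = list(range(2, 2 + len(self.carbons)))


@dataclass
class MoleculeRecord:
    id: int
    species: str
    atoms: tuple[int, int]  # [start, stop) atom index range
    head: int  # phosphorus (DPPC) or hydroxyl oxygen (sterols)
    chains: list[ChainSpec] = field(default_factory=list)
    ring: list[int] = field(default_factory=list)
    methyl_marker: int | None = None  # atom on the rough beta-face side

    @property
    def is_sterol(self) -> bool:
        return self.species in STEROLS


@dataclass
class Topology:
    """Roles of atoms per molecule; validated against a particle count."""

    n_particles: int
    molecules: list[MoleculeRecord]

    def __post_init__(self) -> None:
        for mol in self.molecules:
            self._validate(mol)

    def _validate(self, mol: MoleculeRecord) -> None:
        idx = [mol.head, *mol.ring]
        for ch in mol.chains:
            idx.extend(ch.carbons)
            for hs in ch.hydrogens:
                idx.extend(hs)
        if mol.methyl_marker is not None:
            idx.append(mol.methyl_marker)
        idx.extend(mol.atoms)
        bad = [i for i in idx if not (0 <= i <= self.n_particles)]
        if any(i >= self.n_particles for i in idx if i not in mol.atoms) or bad:
            raise TopologyError(
                f"molecule {mol.id}: atom index out of range (n_particles={self.n_particles})"
            )
        if mol.species == "DPPC" and len(mol.chains) != 2:
            raise TopologyError(f"molecule {mol.id}: DPPC must have exactly two chains")
        if mol.is_sterol and not mol.ring:
            raise TopologyError(f"molecule {mol.id}: sterol must list ring atoms")

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def by_species(self, *species: str) -> list[MoleculeRecord]:
        return [m for m in self.molecules if m.species in species]

    def sterols(self) -> list[MoleculeRecord]:
        return [m for m in self.molecules if m.is_sterol]


@dataclass
class Trajectory:
    """Ordered frames with a fixed particle count and uniform time spacing."""

    frames: list[Frame]
    dt: float | None = None  # ns; inferred from times when omitted

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("trajectory must contain at least one frame")
        n0 = self.frames[0].n_particles
        for k, fr in enumerate(self.frames):
            if fr.n_particles != n0:
                raise StructureError(
                    f"frame {k} has {fr.n_particles} particles, expected {n0}"
                )
        times = self.times
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise StructureError("frame times must be strictly increasing")
            if self.dt is None:
                self.dt = float(np.median(steps))
            if not np.allclose(steps, self.dt, rtol=0, atol=1e-6 + 1e-3 * self.dt):
                raise StructureError("frame spacing is not uniform")
        elif self.dt is None:
            self.dt = 0.0

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_particles(self) -> int:
        return self.frames[0].n_particles

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def box(self) -> tuple[float, float, float]:
        return self.frames[0].box

    def positions_array(self) -> np.ndarray:
        """(n_frames, N, 3) stacked positions."""
        return np.stack([f.positions for f in self.frames])

    def frame_index(self, t: float) -> int:
        times = self.times
        k = int(np.argmin(np.abs(times - t)))
        if abs(times[k] - t) > 1e-6 + 1e-3 * (self.dt or 1.0):
            raise ValueError(f"time {t} ns not on the frame grid")
        return k


@dataclass
class LeafletAssignment:
    """Per-frame leaflet label of every molecule plus the midplane surface.

    ``labels``: (n_frames, n_molecules) int8, +1 upper / -1 lower / 0 not a
    lipid.  ``static_labels``: the per-molecule majority label used where a
    single label per molecule is required (DPPC labels are constant over the
    analysis window; sterols may flip).
    """

    labels: np.ndarray
    static_labels: np.ndarray
    midplane: GridMap

    def molecules_in(self, leaflet: str) -> np.ndarray:
        want = 1 if leaflet == "upper" else -1
        return np.where(self.static_labels == want)[0]


def reference_point(mol: MoleculeRecord, positions: np.ndarray) -> np.ndarray:
    """Molecule reference point: DPPC = phosphorus, sterol = ring centroid."""
    if mol.is_sterol:
        return positions[mol.ring].mean(axis=0)
    return positions[mol.head]


def reference_points(top: Topology, positions: np.ndarray) -> np.ndarray:
    """(n_molecules, 3) reference points for one frame."""
    return np.stack([reference_point(m, positions) for m in top.molecules])
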