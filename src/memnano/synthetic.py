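"""Synthetic bilayer trajectories with controlled statistical structure.

The generator builds toy membranes that reproduce, by construction, the
statistics the analysis stages consume: per-region target chain order,
headgroup heights (thickness), lattice packing (hexagonal core vs jittered
fluid), cholesterol placement, interleaflet registration, per-region lateral
mobility, scripted cholesterol flip-flops, and optional ripples.  Chains are
rigid rods with decorative hydrogens — the point is verifiable statistics,
not molecular realism.

Order-parameter construction
----------------------------
Each chain is a straight run of carbons along an axis tilted by ``beta`` from
the membrane normal; the two hydrogens of every carbon point along two
mutually orthogonal directions perpendicular to the axis.  The mean of
``P2(cos theta)`` over such an orthogonal pair is exactly ``-1/2 P2(cos
beta)`` in every frame, so a single tilt angle with ``cos^2 beta =
(4 S_target + 1)/3`` realizes the requested time-averaged ``-S_CD = S_target``
for any physical target in [0, 0.5] (targets below -0.25 would need a
two-point beta mixture; they are outside the reporting range and rejected).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from scipy.spatial import cKDTree

from .grids import minimum_image, periodic_point_distance
from .model import ChainSpec, Frame, MoleculeRecord, Topology, Trajectory
from .order import DEFAULT_BINS, OrderDistribution

CC_SPACING = 0.127  # nm between consecutive chain carbons
CH_LENGTH = 0.109  # nm C-H bond
HEAD_GAP = 0.35  # nm from phosphate plane down to the first chain carbon
RING_HALF_HEIGHT = 0.25  # nm sterol ring half-extent along z
RING_HALF_WIDTH = 0.18  # nm sterol ring half-extent in-plane
RING_Z = 0.8  # nm |ring centroid| above/below the midplane
MARKER_OFFSET = 0.15  # nm methyl marker off the ring plane


class ConfigError(ValueError):
    """Invalid synthetic-bilayer configuration."""


@dataclass
class RegionSpec:
    """One lateral region of a leaflet.

    ``geometry`` is either ``"background"`` or ``("disc", (cx, cy), radius)``.
    ``thickness_offset`` is the |z| of the phosphate plane (half-thickness).
    ``s_target`` is the region's time-averaged -S_CD; ``s_sigma`` spreads it
    per chain.  ``sigma_step`` is the per-frame random-walk step (mobility).
    """

    label: str  # core | ordered | disordered
    geometry: object
    thickness_offset: float
    s_target: float
    packing: str = "jittered"  # hexagonal | jittered
    lattice_constant: float = 0.6
    jitter_sigma: float = 0.02  # static in-plane wobble of lattice sites
    chol_fraction: float = 0.0
    sigma_step: float = 0.0
    s_sigma: float = 0.0

    def validate(self, box) -> None:
        if not 0.0 <= self.s_target <= 0.5:
            raise ConfigError(f"region {self.label}: S_target must be in [0, 0.5]")
        if not 0.0 <= self.chol_fraction <= 1.0:
            raise ConfigError(f"region {self.label}: chol_fraction must be in [0, 1]")
        if self.geometry != "background":
            kind, _, radius = self.geometry
            if kind != "disc":
                raise ConfigError(f"region {self.label}: unknown geometry {kind!r}")
            if radius > 0.5 * min(box[0], box[1]):
                raise ConfigError(
                    f"region {self.label}: disc does not fit the periodic box"
                )

    def contains(self, xy, box) -> bool:
        if self.geometry == "background":
            return True
        _, centre, radius = self.geometry
        return float(periodic_point_distance(np.asarray(xy), np.asarray(centre),
                                             box[:2])) <= radius


@dataclass
class SyntheticConfig:
    box: tuple[float, float, float]
    regions_upper: list[RegionSpec]
    regions_lower: list[RegionSpec]
    registration: str = "registered"  # registered | antiregistered | independent
    n_frames: int = 50
    dt: float = 0.1  # ns
    n_carbons: int = 6
    seed: int = 0
    flip_events: list[tuple[int, float]] = field(default_factory=list)  # (sterol ordinal, ns)
    feints: list[tuple[int, float, float]] = field(default_factory=list)  # (ordinal, ns, depth nm)
    ripple_amplitude: float = 0.0
    ripple_waves: int = 1
    shrink: dict | None = None  # {"label": region label, "T": ns}
    sterol_face: str = "random"  # random | toward_disordered

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        for rs in (*self.regions_upper, *self.regions_lower):
            rs.validate(self.box)
        if self.registration not in ("registered", "antiregistered", "independent"):
            raise ConfigError(f"unknown registration mode {self.registration!r}")
        if self.registration != "independent":
            if len(self.regions_upper) != len(self.regions_lower):
                raise ConfigError("registered modes need matching region layouts")
            for a, b in zip(self.regions_upper, self.regions_lower):
                if a.geometry != b.geometry:
                    raise ConfigError(
                        "registered modes require identical region geometry per leaflet"
                    )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, default_flow_style=None)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("regions_upper", "regions_lower"):
            d[key] = [RegionSpec(**_tuplify_geometry(r)) for r in d[key]]
        d["box"] = tuple(d["box"])
        d["flip_events"] = [tuple(e) for e in d.get("flip_events", [])]
        d["feints"] = [tuple(e) for e in d.get("feints", [])]
        return cls(**d)


def _tuplify_geometry(rdict: dict) -> dict:
    g = rdict.get("geometry")
    if isinstance(g, list):
        rdict = dict(rdict)
        rdict["geometry"] = (g[0], tuple(g[1]), g[2])
    return rdict


@dataclass
class GroundTruth:
    """What the generator actually built, for verification."""

    molecules: list[dict]  # id, species, leaflet, region, sites [[x, y], ...]
    flip_events: list[dict]  # molecule_id, time, direction
    region_geometry: dict  # leaflet -> list of (label, geometry)
    config: SyntheticConfig

    def molecules_where(self, **conds) -> list[dict]:
        return [m for m in self.molecules
                if all(m.get(k) == v for k, v in conds.items())]

    def interior_core_sites(self, leaflet: str = "upper",
                            margin: float | None = None) -> np.ndarray:
        """Lateral chain sites of the core region at least one lattice spacing
        inside the core disc (their full first shell lies in the core)."""
        geo = dict(self.region_geometry[leaflet]).get("core")
        if geo is None or geo == "background":
            raise ValueError("no core disc in this fixture")
        _, centre, radius = geo
        core_a = [r for r in (self.config.regions_upper
                              if leaflet == "upper" else self.config.regions_lower)
                  if r.label == "core"][0].lattice_constant
        if margin is None:
            margin = 1.5 * core_a
        pts = []
        box2 = np.asarray(self.config.box[:2])
        for m in self.molecules_where(leaflet=leaflet, region="core"):
            for s in m["sites"]:
                if periodic_point_distance(np.asarray(s), np.asarray(centre),
                                           box2) <= radius - margin:
                    pts.append(s)
        return np.asarray(pts) if pts else np.empty((0, 2))

    def to_json(self, path) -> None:
        d = {
            "molecules": self.molecules,
            "flip_events": self.flip_events,
            "region_geometry": {
                lf: [[lb, list(g) if g != "background" else g] for lb, g in pairs]
                for lf, pairs in
                ((k, v) for k, v in self.region_geometry.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(d, fh, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(type(o).__name__)


# ---------------------------------------------------------------------------
# lattice and layout

def _lattice_sites(box, a: float, rng, jitter: float) -> np.ndarray:
    """Hexagonal lattice covering the lateral box, with static Gaussian wobble."""
    dy = a * np.sqrt(3.0) / 2.0
    nrow = max(1, int(box[1] / dy))
    ncol = max(1, int(box[0] / a))
    pts = []
    for r in range(nrow):
        x0 = (a / 2.0) * (r % 2)
        for c in range(ncol):
            pts.append((x0 + c * a, r * dy))
    pts = np.asarray(pts, dtype=float)
    if jitter > 0:
        pts = pts + rng.normal(0.0, jitter, pts.shape)
    return np.mod(pts, (box[0], box[1]))


def _pair_nearest(sites: np.ndarray, box2) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour pairing of chain sites into two-chain lipids.

    Keeps the two chains of a molecule laterally adjacent so the headgroup
    (placed at the pair midpoint) stays inside the pair's region.
    """
    n = sites.shape[0]
    if n < 2:
        return []
    box2 = (float(box2[0]), float(box2[1]))
    wrapped = np.mod(sites, box2)
    tree = cKDTree(wrapped, boxsize=box2)
    used = np.zeros(n, dtype=bool)
    pairs = []
    order = np.lexsort((sites[:, 0], sites[:, 1]))
    for i in order:
        if used[i]:
            continue
        used[i] = True
        k = min(n, 9)
        _, idxs = tree.query(wrapped[i], k=k)
        partner = next((int(j) for j in np.atleast_1d(idxs)
                        if j != i and not used[j]), None)
        if partner is None:
            rem = np.nonzero(~used)[0]
            if rem.size == 0:
                break
            d = periodic_point_distance(sites[rem], sites[i], np.asarray(box2))
            partner = int(rem[np.argmin(d)])
        used[partner] = True
        pairs.append((int(i), partner))
    return pairs


def _periodic_midpoint(a: np.ndarray, b: np.ndarray, box2) -> np.ndarray:
    box2 = np.asarray(box2, dtype=float)
    return np.mod(a + 0.5 * minimum_image(b - a, box2), box2)


def _assign_region(xy, regions: list[RegionSpec], box) -> int:
    for k, rs in enumerate(regions):
        if rs.geometry != "background" and rs.contains(xy, box):
            return k
    for k, rs in enumerate(regions):
        if rs.geometry == "background":
            return k
    return -1


def _leaflet_layout(regions: list[RegionSpec], box, rng) -> list[tuple[int, np.ndarray, bool]]:
    """Place chain sites and decide species.

    Returns a list of molecules as (region index, sites (k, 2), is_sterol):
    DPPC molecules own two adjacent sites, sterols one.
    """
    per_region_sites: list[np.ndarray] = []
    for k, rs in enumerate(regions):
        jitter = rs.jitter_sigma if rs.packing == "jittered" else min(rs.jitter_sigma, 0.02)
        sites = _lattice_sites(box, rs.lattice_constant, rng, jitter)
        keep = np.array([_assign_region(p, regions, box) == k for p in sites])
        per_region_sites.append(sites[keep])
    molecules = []
    for k, (rs, sites) in enumerate(zip(regions, per_region_sites)):
        n = sites.shape[0]
        if n == 0:
            continue
        f = rs.chol_fraction
        n_chol = int(round(f * n / (2.0 - f)))
        if n_chol > n:
            raise ConfigError(
                f"region {rs.label}: cholesterol fraction incompatible with "
                f"lattice occupancy ({n_chol} sterols for {n} sites)"
            )
        order = np.lexsort((sites[:, 0], sites[:, 1]))
        sites = sites[order]
        chol_pick = rng.choice(n, size=n_chol, replace=False) if n_chol else np.empty(0, int)
        is_chol = np.zeros(n, dtype=bool)
        is_chol[chol_pick] = True
        for i in np.nonzero(is_chol)[0]:
            molecules.append((k, sites[i:i + 1], True))
        rest = sites[~is_chol]
        if rest.shape[0] % 2 == 1 and rest.shape[0] > 0:
            # odd leftover: drop the site farthest from the disc centre (or the
            # last site for a background region) so interior packing is intact
            if rs.geometry != "background":
                _, centre, _ = rs.geometry
                d = periodic_point_distance(rest, np.asarray(centre), np.asarray(box[:2]))
                drop = int(np.argmax(d))
            else:
                drop = rest.shape[0] - 1
            rest = np.delete(rest, drop, axis=0)
        for i, j in _pair_nearest(rest, box[:2]):
            molecules.append((k, rest[[i, j]], False))
    if not molecules:
        raise ConfigError("configuration produced no molecules")
    return molecules


# ---------------------------------------------------------------------------
# generation

def generate(config: SyntheticConfig):
    """Build (Trajectory, Topology, GroundTruth) from a synthetic config.

    The seed fully determines the output; the same config generates bitwise
    identical trajectories.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    box = config.box
    midz = box[2] / 2.0

    layouts = {}
    layout_rng_state = rng.bit_generator.state
    layouts["upper"] = _leaflet_layout(config.regions_upper, box, rng)
    if config.registration == "independent":
        layouts["lower"] = _leaflet_layout(config.regions_lower, box, rng)
    else:
        # mirrored site layout: same lateral structure in both leaflets
        saved = rng.bit_generator.state
        rng.bit_generator.state = layout_rng_state
        layouts["lower"] = _leaflet_layout(config.regions_lower, box, rng)
        rng.bit_generator.state = saved

    mol_records: list[MoleculeRecord] = []
    gt_mols: list[dict] = []
    base_pos: list[np.ndarray] = []
    mol_of_atom: list[int] = []
    names: list[tuple[int, str, str]] = []

    # chain bookkeeping for per-frame hydrogen placement
    chain_e1, chain_e2 = [], []
    chain_c_idx, chain_h_idx = [], []
    sterols: list[int] = []  # molecule index per sterol ordinal
    mol_sigma, mol_sign, mol_region, mol_leaflet = [], [], [], []
    sterol_base_z: dict[int, float] = {}

    nc = config.n_carbons
    atom_counter = 0
    mol_id = 0
    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        regions = config.regions_upper if leaflet == "upper" else config.regions_lower
        for region_idx, sites, is_sterol in layouts[leaflet]:
            rs = regions[region_idx]
            start = atom_counter
            if is_sterol:
                cx, cy = sites[0]
                cz = midz + sign * RING_Z
                if config.sterol_face == "toward_disordered" and rs.geometry != "background":
                    _, centre, _ = rs.geometry
                    d = np.array([cx, cy]) - np.asarray(centre)
                    d = d - np.asarray(box[:2]) * np.round(d / np.asarray(box[:2]))
                    nrm = np.hypot(*d)
                    face = d / nrm if nrm > 1e-9 else np.array([1.0, 0.0])
                else:
                    ang = rng.uniform(0, 2 * np.pi)
                    face = np.array([np.cos(ang), np.sin(ang)])
                ring_v = np.array([-face[1], face[0]])  # ring plane contains z and ring_v
                atoms = [
                    np.array([cx, cy, cz + sign * (RING_HALF_HEIGHT + 0.25)]),  # hydroxyl O
                    np.array([cx + RING_HALF_WIDTH * ring_v[0],
                              cy + RING_HALF_WIDTH * ring_v[1], cz]),
                    np.array([cx - RING_HALF_WIDTH * ring_v[0],
                              cy - RING_HALF_WIDTH * ring_v[1], cz]),
                    np.array([cx, cy, cz + RING_HALF_HEIGHT]),
                    np.array([cx, cy, cz - RING_HALF_HEIGHT]),
                    np.array([cx + MARKER_OFFSET * face[0],
                              cy + MARKER_OFFSET * face[1], cz]),
                ]
                for a in atoms:
                    base_pos.append(a)
                    mol_of_atom.append(mol_id)
                names.extend(
                    (mol_id + 1, "CHOL", nm)
                    for nm in ("O3", "R1", "R2", "R3", "R4", "C18")
                )
                atom_counter += 6
                mol_records.append(MoleculeRecord(
                    id=mol_id, species="CHOL", atoms=(start, atom_counter),
                    head=start, ring=[start + 1, start + 2, start + 3, start + 4],
                    methyl_marker=start + 5,
                ))
                sterols.append(mol_id)
                sterol_base_z[mol_id] = sign * RING_Z
            else:
                head_xy = _periodic_midpoint(sites[0], sites[1], box[:2])
                head_z = midz + sign * rs.thickness_offset
                base_pos.append(np.array([head_xy[0], head_xy[1], head_z]))
                mol_of_atom.append(mol_id)
                names.append((mol_id + 1, "DPPC", "P"))
                atom_counter += 1
                chains = []
                for ci, site in enumerate(sites):
                    s_chain = rs.s_target if rs.s_sigma == 0 else float(
                        np.clip(rng.normal(rs.s_target, rs.s_sigma), 0.0, 0.5))
                    cosb = np.sqrt((4.0 * s_chain + 1.0) / 3.0)
                    sinb = np.sqrt(max(0.0, 1.0 - cosb ** 2))
                    phi = rng.uniform(0, 2 * np.pi)
                    axis = np.array([sinb * np.cos(phi), sinb * np.sin(phi),
                                     -sign * cosb])
                    # orthonormal pair perpendicular to the chain axis
                    helper = np.array([0.0, 0.0, 1.0])
                    if abs(axis[2]) > 0.999:
                        helper = np.array([1.0, 0.0, 0.0])
                    e1 = np.cross(axis, helper)
                    e1 /= np.linalg.norm(e1)
                    e2 = np.cross(axis, e1)
                    # centre the chain laterally on its site so the measured
                    # chain-site centroid sits on the lattice regardless of tilt
                    z_top = midz + sign * (rs.thickness_offset - HEAD_GAP)
                    lat0 = site - axis[:2] * (CC_SPACING * (nc - 1) / 2.0)
                    c_idx, h_idx = [], []
                    for k in range(nc):
                        cpos = np.array([
                            lat0[0] + axis[0] * CC_SPACING * k,
                            lat0[1] + axis[1] * CC_SPACING * k,
                            z_top + axis[2] * CC_SPACING * k,
                        ])
                        base_pos.append(cpos)
                        mol_of_atom.append(mol_id)
                        names.append((mol_id + 1, "DPPC", f"C{ci + 1}{k + 2}"))
                        c_i = atom_counter
                        atom_counter += 1
                        hs = []
                        for hh in range(2):
                            base_pos.append(cpos + CH_LENGTH * (e1 if hh == 0 else e2))
                            mol_of_atom.append(mol_id)
                            names.append((mol_id + 1, "DPPC", f"H{ci + 1}{k + 2}{hh}"))
                            hs.append(atom_counter)
                            atom_counter += 1
                        c_idx.append(c_i)
                        h_idx.append(hs)
                    chains.append(ChainSpec(
                        label="sn-1" if ci == 0 else "sn-2",
                        carbons=c_idx, hydrogens=h_idx,
                        carbon_numbers=list(range(2, 2 + nc)),
                    ))
                    chain_e1.append(e1)
                    chain_e2.append(e2)
                    chain_c_idx.append(c_idx)
                    chain_h_idx.append(h_idx)
                mol_records.append(MoleculeRecord(
                    id=mol_id, species="DPPC", atoms=(start, atom_counter),
                    head=start, chains=chains,
                ))
            gt_mols.append({
                "id": mol_id, "species": "CHOL" if is_sterol else "DPPC",
                "leaflet": leaflet, "region": regions[region_idx].label,
                "sites": [list(map(float, s)) for s in sites],
            })
            mol_sigma.append(regions[region_idx].sigma_step)
            mol_sign.append(sign)
            mol_region.append(regions[region_idx].label)
            mol_leaflet.append(leaflet)
            mol_id += 1

    n_atoms = atom_counter
    n_mols = mol_id
    base = np.asarray(base_pos)
    mol_of_atom = np.asarray(mol_of_atom)
    mol_sigma = np.asarray(mol_sigma)
    chain_e1 = np.asarray(chain_e1) if chain_e1 else np.empty((0, 3))
    chain_e2 = np.asarray(chain_e2) if chain_e2 else np.empty((0, 3))
    chain_c_idx = np.asarray(chain_c_idx, dtype=int) if chain_c_idx else np.empty((0, nc), int)
    chain_h_idx = np.asarray(chain_h_idx, dtype=int) if chain_h_idx else np.empty((0, nc, 2), int)

    flip_sched, gt_flips = _flip_schedule(config, sterols, mol_records,
                                          sterol_base_z, gt_mols)
    shrink_info = _shrink_info(config, gt_mols, mol_records, box)

    times = np.arange(config.n_frames) * config.dt
    walk = np.zeros((n_mols, 2))
    frames: list[Frame] = []
    for fi, t in enumerate(times):
        if fi > 0:
            steps = rng.normal(0.0, 1.0, (n_mols, 2)) * mol_sigma[:, None]
            walk = walk + steps
        pos = base.copy()
        pos[:, :2] += walk[mol_of_atom]
        # scripted sterol z-motion (flips and feints)
        for mid, zfun in flip_sched.items():
            dz = zfun(t) - sterol_base_z[mid]
            if dz != 0.0:
                pos[mol_of_atom == mid, 2] += dz
        # shrinking disc: heads outside the current radius take the fallback height
        if shrink_info is not None:
            _apply_shrink(pos, shrink_info, walk, t, midz)
        # per-frame hydrogen azimuth (exactness does not depend on it)
        if chain_c_idx.size:
            phis = rng.uniform(0, 2 * np.pi, chain_e1.shape[0])
            u1 = np.cos(phis)[:, None] * chain_e1 + np.sin(phis)[:, None] * chain_e2
            u2 = -np.sin(phis)[:, None] * chain_e1 + np.cos(phis)[:, None] * chain_e2
            cpos = pos[chain_c_idx]  # (n_ch, nc, 3)
            pos[chain_h_idx[:, :, 0]] = cpos + CH_LENGTH * u1[:, None, :]
            pos[chain_h_idx[:, :, 1]] = cpos + CH_LENGTH * u2[:, None, :]
        if config.ripple_amplitude:
            pos[:, 2] += config.ripple_amplitude * np.sin(
                2 * np.pi * config.ripple_waves * pos[:, 0] / box[0])
        frames.append(Frame(float(t), pos, box))

    traj = Trajectory(frames, dt=config.dt)
    top = Topology(n_particles=n_atoms, molecules=mol_records)
    gt = GroundTruth(
        molecules=gt_mols,
        flip_events=gt_flips,
        region_geometry={
            "upper": [(r.label, r.geometry) for r in config.regions_upper],
            "lower": [(r.label, r.geometry) for r in config.regions_lower],
        },
        config=config,
    )
    traj._names = names  # stashed for file export
    return traj, top, gt


def _flip_schedule(config, sterols, mol_records, sterol_base_z, gt_mols):
    """Per-sterol scripted z(t): committed flips plus shallow feints."""
    ramp = 2 * config.dt  # crossing takes two frames
    sched: dict[int, object] = {}
    gt_flips = []
    by_ordinal: dict[int, dict] = {}
    for ordinal, t_ev in config.flip_events:
        if ordinal >= len(sterols):
            raise ConfigError(f"flip event names sterol ordinal {ordinal}, "
                              f"but only {len(sterols)} sterols exist")
        by_ordinal.setdefault(ordinal, {"flips": [], "feints": []})["flips"].append(t_ev)
    for ordinal, t_ev, depth in config.feints:
        if ordinal >= len(sterols):
            raise ConfigError(f"feint names sterol ordinal {ordinal}")
        by_ordinal.setdefault(ordinal, {"flips": [], "feints": []})["feints"].append(
            (t_ev, depth))
    for ordinal, ev in by_ordinal.items():
        mid = sterols[ordinal]
        z0 = sterol_base_z[mid]
        flips = sorted(ev["flips"])
        feints = ev["feints"]

        def zfun(t, z0=z0, flips=flips, feints=feints):
            z = z0
            sign = 1.0
            for tf in flips:
                if t >= tf + ramp:
                    sign = -sign
                elif t > tf - ramp:
                    frac = (t - (tf - ramp)) / (2 * ramp)
                    return z0 * sign * (1.0 - 2.0 * frac)
            z = z0 * sign
            for tf, depth in feints:
                if abs(t - tf) < ramp:
                    dip = depth * (1.0 - abs(t - tf) / ramp)
                    return z - np.sign(z) * dip
            return z

        sched[mid] = zfun
        side0 = "upper" if z0 > 0 else "lower"
        cur = side0
        for tf in flips:
            nxt = "lower" if cur == "upper" else "upper"
            gt_flips.append({"molecule_id": mid, "time": float(tf),
                             "direction": f"{cur}->{nxt}"})
            cur = nxt
    return sched, gt_flips


def _shrink_info(config, gt_mols, mol_records, box):
    if config.shrink is None:
        return None
    label = config.shrink["label"]
    T = float(config.shrink["T"])
    regions = config.regions_upper
    shrink_rs = next((r for r in regions if r.label == label), None)
    if shrink_rs is None or shrink_rs.geometry == "background":
        raise ConfigError("shrink must name a disc region present in both leaflets")
    _, centre, r0 = shrink_rs.geometry
    fallback = next((r for r in regions if r.geometry == "background"), None)
    if fallback is None:
        raise ConfigError("shrink needs a background region as fallback")
    affected = []  # (head atom index, distance from centre, sign)
    for gm, mrec in zip(gt_mols, mol_records):
        if gm["region"] != label or mrec.species != "DPPC":
            continue
        xy = _periodic_midpoint(np.asarray(gm["sites"][0]),
                                np.asarray(gm["sites"][1]), box[:2])
        d = float(periodic_point_distance(xy, np.asarray(centre), np.asarray(box[:2])))
        affected.append((mrec.head, d, 1.0 if gm["leaflet"] == "upper" else -1.0))
    return {"T": T, "r0": r0, "affected": affected,
            "fallback_offset": fallback.thickness_offset,
            "shrink_offset": shrink_rs.thickness_offset}


def _apply_shrink(pos, info, walk, t, midz):
    r_t = info["r0"] * np.sqrt(max(0.0, 1.0 - t / (2.0 * info["T"])))
    for head_idx, dist, sign in info["affected"]:
        if dist > r_t:
            pos[head_idx, 2] = midz + sign * info["fallback_offset"]


# ---------------------------------------------------------------------------
# parametric reference distributions

#: documented per-phase parameters of the parametric reference distributions:
#: (-S_CD mean at carbon 2, fractional decay toward the terminal carbon,
#:  per-chain spread).  Gel is narrow and high, Lo intermediate, Ld broad/low.
PHASE_PARAMS = {
    "gel": (0.42, 0.05, 0.015),
    "Lo": (0.33, 0.15, 0.030),
    "Ld": (0.18, 0.35, 0.050),
}


def reference_distribution(
    phase: str,
    carbons: list[int] | None = None,
    n_chains: int = 20000,
    seed: int = 0,
    bins: np.ndarray = DEFAULT_BINS,
) -> OrderDistribution:
    """Parametric per-carbon order distribution of a homogeneous phase.

    Stands in for distributions measured on homogeneous single-phase
    reference membranes; means satisfy gel > Lo > Ld at every carbon.
    """
    if phase not in PHASE_PARAMS:
        raise ValueError(f"unknown phase {phase!r}; expected one of {list(PHASE_PARAMS)}")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    carbons = list(carbons) if carbons is not None else list(range(2, 16))
    base, decay, sigma = PHASE_PARAMS[phase]
    rng = np.random.default_rng(seed)
    n = len(carbons)
    hists = np.empty((n, len(bins) - 1))
    for k in range(n):
        frac = k / max(n - 1, 1)
        mean = base * (1.0 - decay * frac)
        vals = np.clip(rng.normal(mean, sigma, n_chains), bins[0], bins[-1])
        h, _ = np.histogram(vals, bins=bins)
        hists[k] = h / h.sum()
    return OrderDistribution(carbons, np.asarray(bins, dtype=float), hists,
                             provenance={"phase": phase, "n_chains": n_chains,
                                         "seed": seed})
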