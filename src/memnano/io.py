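"""Coordinate and topology file I/O.

Formats
-------
GRO
    Fixed-width Gromacs coordinate files, nm, multi-frame by concatenation.
    The frame time is read from a ``t=`` tag in the title line when present.
    Only orthorhombic boxes (three box numbers, or nine with zero
    off-diagonals) are supported.
XYZ
    Plain XYZ (Angstrom, converted to nm on read) with a JSON side-car
    ``<file>.box.json`` holding ``{"schema": 1, "box_nm": [Lx, Ly, Lz]}``.
Topology
    An explicit JSON side-car (``"schema": 1``) declaring per-molecule atom
    roles, rather than inference from atom names: force-field agnostic and
    directly testable.  See ``Topology`` for the semantics of each field.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .model import (
    ChainSpec,
    Frame,
    MoleculeRecord,
    StructureError,
    Topology,
    Trajectory,
)

ANGSTROM_PER_NM = 10.0
_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


class ParseError(ValueError):
    """Malformed record in a coordinate file; message names the line."""


class UnsupportedFormatError(ValueError):
    """Input uses a dialect the reader does not support (e.g. triclinic box)."""


# ---------------------------------------------------------------------------
# GRO

def _parse_gro_box(line: str, lineno: int) -> tuple[float, float, float]:
    try:
        vals = [float(tok) for tok in line.split()]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed box line: {line!r}") from exc
    if len(vals) == 3:
        return (vals[0], vals[1], vals[2])
    if len(vals) == 9:
        if any(abs(v) > 1e-9 for v in vals[3:]):
            raise UnsupportedFormatError(
                f"line {lineno}: triclinic boxes are not supported"
            )
        return (vals[0], vals[1], vals[2])
    raise ParseError(f"line {lineno}: box line must have 3 or 9 numbers")


def _read_gro(path: Path) -> list[tuple[float | None, np.ndarray, tuple]]:
    frames = []
    lines = path.read_text().splitlines()
    i = 0
    nframe = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        title = lines[i]
        m = _TIME_RE.search(title)
        time = float(m.group(1)) if m else None
        try:
            natoms = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise ParseError(f"line {i + 2}: expected atom count") from exc
        if i + 2 + natoms >= len(lines) + 0 and len(lines) < i + 3 + natoms:
            raise ParseError(f"frame {nframe}: truncated (expected {natoms} atoms)")
        pos = np.empty((natoms, 3))
        for k in range(natoms):
            ln = lines[i + 2 + k]
            lineno = i + 3 + k
            try:
                pos[k, 0] = float(ln[20:28])
                pos[k, 1] = float(ln[28:36])
                pos[k, 2] = float(ln[36:44])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: malformed atom record: {ln!r}") from exc
        box = _parse_gro_box(lines[i + 2 + natoms], i + 3 + natoms)
        frames.append((time, pos, box))
        i += natoms + 3
        nframe += 1
    if not frames:
        raise ParseError("no frames found in GRO file")
    return frames


def _write_gro(traj: Trajectory, path: Path, names) -> None:
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"memnano frame t= {fr.time:.6f}\n")
            fh.write(f"{fr.n_particles:5d}\n")
            for k in range(fr.n_particles):
                resid, resname, atomname = names[k] if names else (k % 99999 + 1, "SYS", "X")
                x, y, z = fr.positions[k]
                fh.write(
                    f"{resid % 100000:5d}{resname:<5.5s}{atomname:>5.5s}"
                    f"{(k + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# XYZ

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".box.json")


def _read_xyz(path: Path) -> list[tuple[float | None, np.ndarray, tuple]]:
    side = _sidecar_path(path)
    if not side.exists():
        raise ParseError(f"XYZ input requires a box side-car at {side}")
    meta = json.loads(side.read_text())
    box = tuple(float(v) for v in meta["box_nm"])
    lines = path.read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: expected atom count") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _TIME_RE.search(comment)
        time = float(m.group(1)) if m else None
        if len(lines) < i + 2 + natoms:
            raise ParseError(f"line {i + 1}: truncated XYZ frame")
        pos = np.empty((natoms, 3))
        for k in range(natoms):
            toks = lines[i + 2 + k].split()
            if len(toks) < 4:
                raise ParseError(f"line {i + 3 + k}: malformed XYZ record")
            try:
                pos[k] = [float(toks[1]), float(toks[2]), float(toks[3])]
            except ValueError as exc:
                raise ParseError(f"line {i + 3 + k}: malformed XYZ record") from exc
        frames.append((time, pos / ANGSTROM_PER_NM, box))
        i += natoms + 2
    if not frames:
        raise ParseError("no frames found in XYZ file")
    return frames


def _write_xyz(traj: Trajectory, path: Path, names) -> None:
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{fr.n_particles}\n")
            fh.write(f"memnano frame t= {fr.time:.6f} ns\n")
            for k in range(fr.n_particles):
                el = names[k][2][:1] if names else "C"
                x, y, z = fr.positions[k] * ANGSTROM_PER_NM
                fh.write(f"{el or 'C'} {x:.5f} {y:.5f} {z:.5f}\n")
    _sidecar_path(path).write_text(
        json.dumps({"schema": 1, "box_nm": list(traj.box)})
    )


# ---------------------------------------------------------------------------
# public API

def read_trajectory(path, format: str | None = None, dt: float | None = None) -> Trajectory:
    """Read a GRO or XYZ trajectory.

    Frames missing a ``t=`` time tag are numbered consecutively with spacing
    ``dt`` (default 1 ns).  Coordinates are returned as stored (not wrapped).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "gro":
        raw = _read_gro(path)
    elif fmt == "xyz":
        raw = _read_xyz(path)
    else:
        raise UnsupportedFormatError(f"unknown trajectory format: {fmt!r}")
    step = dt if dt is not None else 1.0
    frames = []
    for k, (time, pos, box) in enumerate(raw):
        frames.append(Frame(time if time is not None else k * step, pos, box))
    n0 = frames[0].n_particles
    for k, fr in enumerate(frames):
        if fr.n_particles != n0:
            raise StructureError(
                f"frame {k} has {fr.n_particles} atoms, expected {n0}"
            )
    return Trajectory(frames, dt=dt)


def write_trajectory(traj: Trajectory, path, format: str | None = None,
                     names: list[tuple[int, str, str]] | None = None) -> None:
    """Write a trajectory as GRO (fixed-width, nm) or XYZ (Angstrom + side-car).

    ``names`` optionally supplies (resid, resname, atomname) per atom.
    """
    if traj.n_frames == 0:
        raise StructureError("cannot write an empty trajectory")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if names is not None and len(names) != traj.n_particles:
        raise ValueError("names must have one entry per particle")
    if fmt == "gro":
        _write_gro(traj, path, names)
    elif fmt == "xyz":
        _write_xyz(traj, path, names)
    else:
        raise UnsupportedFormatError(f"unknown trajectory format: {fmt!r}")


# ---------------------------------------------------------------------------
# topology JSON

def topology_to_dict(top: Topology) -> dict:
    return {
        "schema": 1,
        "n_particles": top.n_particles,
        "molecules": [
            {
                "id": m.id,
                "species": m.species,
                "atoms": list(m.atoms),
                "head": m.head,
                "chains": [
                    {
                        "label": c.label,
                        "carbons": c.carbons,
                        "hydrogens": c.hydrogens,
                        "carbon_numbers": c.carbon_numbers,
                    }
                    for c in m.chains
                ],
                "ring": m.ring,
                "methyl_marker": m.methyl_marker,
            }
            for m in top.molecules
        ],
    }


def save_topology(top: Topology, path) -> None:
    Path(path).write_text(json.dumps(topology_to_dict(top)))


def load_topology(path) -> Topology:
    """Load and validate a schema-1 topology JSON file."""
    data = json.loads(Path(path).read_text())
    if data.get("schema") != 1:
        raise UnsupportedFormatError("topology schema must be 1")
    mols = []
    for rec in data["molecules"]:
        chains = [
            ChainSpec(
                label=c["label"],
                carbons=list(c["carbons"]),
                hydrogens=[list(h) for h in c["hydrogens"]],
                carbon_numbers=list(c["carbon_numbers"]) if c.get("carbon_numbers") else None,
            )
            for c in rec.get("chains", [])
        ]
        mols.append(
            MoleculeRecord(
                id=int(rec["id"]),
                species=rec["species"],
                atoms=tuple(rec["atoms"]),
                head=int(rec["head"]),
                chains=chains,
                ring=list(rec.get("ring", [])),
                methyl_marker=rec.get("methyl_marker"),
            )
        )
    return Topology(n_particles=int(data["n_particles"]), molecules=mols)
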