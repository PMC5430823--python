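"""Cholesterol flip-flop detection and boundary localization.

A sterol's leaflet trace is its ring-centroid height relative to the *local*
midplane (so membrane ripples do not fake events).  A flip-flop is committed
only when the trace, having last been beyond +delta, passes beyond -delta and
stays on the new side for at least tau_min (and symmetrically): the
hysteresis band rejects shallow excursions, the dwell time rejects immediate
recrossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .leaflets import SamplingError
from .model import LeafletAssignment, Topology, Trajectory
from .regions import RegionMap, boundary_distance, boundary_distance_map

DEFAULT_DELTA = 0.4  # nm hysteresis half-width
DEFAULT_TAU_MIN = 1.0  # ns dwell on the new side


@dataclass
class FlipFlopEvent:
    molecule_id: int
    time: float  # ns, first crossing of the far threshold
    direction: str  # "upper->lower" | "lower->upper"
    position: tuple[float, float]  # lateral position at the commit frame, nm
    boundary_distance: float | None = None


def leaflet_trace(
    traj: Trajectory,
    top: Topology,
    assignment: LeafletAssignment,
    mol_index: int,
) -> np.ndarray:
    """Signed ring-centroid height (nm) relative to the local midplane."""
    mol = top.molecules[mol_index]
    ring = mol.ring if mol.is_sterol else [mol.head]
    out = np.empty(traj.n_frames)
    for fi, fr in enumerate(traj.frames):
        c = fr.positions[ring].mean(axis=0)
        out[fi] = c[2] - float(assignment.midplane.value_at(c[:2]))
    return out


def detect_flipflops(
    trace: np.ndarray,
    times: np.ndarray,
    delta: float = DEFAULT_DELTA,
    tau_min: float = DEFAULT_TAU_MIN,
    molecule_id: int = 0,
    positions: np.ndarray | None = None,
) -> list[FlipFlopEvent]:
    """Hysteresis + dwell flip-flop detector on a signed height trace.

    ``positions`` (n_frames, 2), when given, supplies the lateral position
    recorded at each commit frame.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if tau_min < 0:
        raise ValueError("tau_min must be non-negative")
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if trace.shape != times.shape:
        raise ValueError("trace and times must have the same length")
    if times[-1] - times[0] < tau_min:
        raise SamplingError("trace shorter than the dwell time tau_min")

    events: list[FlipFlopEvent] = []
    # current committed side: sign of the first excursion beyond +/- delta
    side = 0
    for i, v in enumerate(trace):
        if side == 0:
            if abs(v) >= delta:
                side = 1 if v > 0 else -1
            continue
        if v * side <= -delta:  # crossed beyond the far threshold
            # commit only if the trace stays on the new side for >= tau_min
            t_commit = times[i]
            j = i
            ok = True
            while j < trace.size and times[j] - t_commit < tau_min - 1e-9:
                if trace[j] * side > 0:  # returned to the old side
                    ok = False
                    break
                j += 1
            if j >= trace.size and times[-1] - t_commit < tau_min - 1e-9:
                ok = False  # ran out of data before the dwell elapsed
            if ok:
                direction = "upper->lower" if side > 0 else "lower->upper"
                pos = (float(positions[i, 0]), float(positions[i, 1])) \
                    if positions is not None else (float("nan"), float("nan"))
                events.append(FlipFlopEvent(molecule_id, float(t_commit),
                                            direction, pos))
                side = -side
    return events


def detect_all_flipflops(
    traj: Trajectory,
    top: Topology,
    assignment: LeafletAssignment,
    delta: float = DEFAULT_DELTA,
    tau_min: float = DEFAULT_TAU_MIN,
) -> list[FlipFlopEvent]:
    """Run the detector over every sterol in the topology."""
    events = []
    times = traj.times
    for k, mol in enumerate(top.molecules):
        if not mol.is_sterol:
            continue
        trace = leaflet_trace(traj, top, assignment, k)
        pos = np.array([fr.positions[mol.ring].mean(axis=0)[:2]
                        for fr in traj.frames])
        events.extend(
            detect_flipflops(trace, times, delta, tau_min,
                             molecule_id=mol.id, positions=pos)
        )
    return sorted(events, key=lambda e: e.time)


def flipflop_boundary_enrichment(
    events: list[FlipFlopEvent],
    region: RegionMap,
    shell_width: float,
) -> dict:
    """Are flip-flops enriched within ``shell_width`` of the domain boundary?

    Compares the fraction of events inside the boundary shell against the
    shell's area fraction (the uniform null) with a one-sided binomial test.
    """
    if not events:
        raise ValueError("no flip-flop events to analyse")
    dmap = boundary_distance_map(region)  # raises on empty boundary
    valid = region.labels != -1
    shell_fraction = float((dmap[valid] <= shell_width).mean())
    if shell_fraction <= 0 or shell_fraction >= 1:
        raise ValueError("shell width leaves no contrast with the null")
    # events are binned to cells and measured with the same cell-centre
    # distance map as the null, so shell membership is consistent
    nx, ny = region.labels.shape
    k = 0
    for ev in events:
        x = np.mod(ev.position[0], region.box[0])
        y = np.mod(ev.position[1], region.box[1])
        ix = min(int(x / region.box[0] * nx), nx - 1)
        iy = min(int(y / region.box[1] * ny), ny - 1)
        d = float(dmap[ix, iy])
        ev.boundary_distance = d
        k += d <= shell_width
    n = len(events)
    ratio = (k / n) / shell_fraction
    test = stats.binomtest(k, n, shell_fraction, alternative="greater")
    return {
        "n_events": n,
        "in_shell": int(k),
        "shell_area_fraction": shell_fraction,
        "enrichment_ratio": float(ratio),
        "p_value": float(test.pvalue),
        "shell_width_nm": float(shell_width),
    }
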