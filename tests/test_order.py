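"""Order-parameter computation: bond geometry, chain averages, distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memnano.model import ChainSpec, Frame, GeometryError, MoleculeRecord, Topology, Trajectory
from memnano.order import (
    DEFAULT_BINS,
    mean_profile,
    order_distribution,
    per_chain_order,
    scd_bond,
)

MAGIC_ANGLE = np.degrees(np.arccos(np.sqrt(1.0 / 3.0)))


@pytest.mark.parametrize("angle_deg,expected", [
    (0.0, 1.0), (90.0, -0.5), (MAGIC_ANGLE, 0.0),
])
def test_scd_bond_reference_angles(angle_deg, expected):
    a = np.radians(angle_deg)
    h = np.array([np.sin(a), 0.0, np.cos(a)]) * 0.109
    assert scd_bond(np.zeros(3), h) == pytest.approx(expected, abs=1e-6)


def test_scd_bond_zero_length_rejected():
    with pytest.raises(GeometryError):
        scd_bond(np.ones(3), np.ones(3))


@given(
    theta=st.floats(0.01, np.pi - 0.01),
    phi=st.floats(0, 2 * np.pi),
    scale=st.floats(0.1, 10.0),
)
@settings(max_examples=50, deadline=None)
def test_scd_bond_invariances(theta, phi, scale):
    """Invariant under rescaling the normal and independent of bond length."""
    b = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
                  np.cos(theta)])
    s1 = scd_bond(np.zeros(3), 0.109 * b, (0, 0, 1))
    s2 = scd_bond(np.zeros(3), 0.25 * b, (0, 0, scale))
    assert s1 == pytest.approx(s2, abs=1e-12)
    assert -0.5 - 1e-12 <= s1 <= 1.0 + 1e-12


def _one_chain_traj(axis_per_frame, box=(5.0, 5.0, 10.0)):
    """One two-carbon sn-2 chain whose axis is prescribed per frame; the two
    hydrogens of each carbon lie along an orthonormal pair normal to the axis."""
    frames = []
    for k, axis in enumerate(axis_per_frame):
        axis = np.asarray(axis, dtype=float)
        axis /= np.linalg.norm(axis)
        helper = np.array([0.0, 0.0, 1.0])
        if abs(axis[2]) > 0.999:
            helper = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(axis, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        pos = np.zeros((7, 3))
        pos[0] = [2.5, 2.5, 7.0]  # P
        for c in range(2):
            cpos = np.array([2.5, 2.5, 6.5]) - axis * 0.127 * c
            pos[1 + 3 * c] = cpos
            pos[2 + 3 * c] = cpos + 0.109 * e1
            pos[3 + 3 * c] = cpos + 0.109 * e2
        frames.append(Frame(0.1 * k, pos, box))
    top = Topology(7, [MoleculeRecord(0, "DPPC", (0, 7), head=0, chains=[
        ChainSpec("sn-1", [1], [[2, 3]]),
        ChainSpec("sn-2", [4], [[5, 6]]),
    ])])
    return Trajectory(frames, dt=0.1), top


def test_chain_along_normal_gives_half():
    traj, top = _one_chain_traj([(0, 0, -1)] * 3)
    pco = per_chain_order(traj, top, None, chain=None)
    assert np.allclose(pco.values, 0.5, atol=1e-12)


def test_isotropic_tumbling_averages_to_zero():
    rng = np.random.default_rng(12)
    n = 10_000
    z = rng.uniform(-1, 1, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - z ** 2)
    axes = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    traj, top = _one_chain_traj(axes)
    pco = per_chain_order(traj, top, None, chain=None)
    assert np.abs(pco.values).max() < 0.02


def test_rotation_about_z_invariance():
    rng = np.random.default_rng(3)
    axes = rng.normal(size=(20, 3))
    traj, top = _one_chain_traj(axes)
    ref = per_chain_order(traj, top, None, chain=None).values
    ang = 1.1
    R = np.array([[np.cos(ang), -np.sin(ang), 0],
                  [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
    rotated = Trajectory([Frame(f.time, f.positions @ R.T, f.box)
                          for f in traj.frames], dt=traj.dt)
    rot = per_chain_order(rotated, top, None, chain=None).values
    assert np.allclose(ref, rot, atol=1e-10)


def _pco_from_values(values):
    """PerChainOrder with prescribed per-chain scalar values at one carbon."""
    from memnano.order import PerChainOrder

    values = np.asarray(values, dtype=float)[:, None]
    return PerChainOrder(
        molecule_ids=np.arange(len(values)),
        chain_labels=["sn-2"] * len(values),
        carbons=[2],
        values=values,
        window=(0.0, 1.0),
        carbon_range=(2, 2),
    )


def test_distribution_single_value_single_bin():
    dist = order_distribution(_pco_from_values([0.25] * 10))
    occupied = np.nonzero(dist.histograms[0])[0]
    assert occupied.size == 1
    lo, hi = dist.bin_edges[occupied[0]], dist.bin_edges[occupied[0] + 1]
    assert lo <= 0.25 < hi
    assert dist.histograms.sum() == pytest.approx(1.0)


def test_distribution_bimodal_equal_mass():
    dist = order_distribution(_pco_from_values([0.1] * 50 + [0.4] * 50))
    centres = dist.bin_centres
    low = dist.histograms[0][centres < 0.25].sum()
    high = dist.histograms[0][centres >= 0.25].sum()
    assert low == pytest.approx(0.5)
    assert high == pytest.approx(0.5)


def test_mean_profile_expectations():
    # expectations are bin-centre quantized: accurate to half a bin (0.005)
    single = order_distribution(_pco_from_values([0.25] * 10))
    assert mean_profile(single).values[0] == pytest.approx(0.25, abs=0.0051)
    bimodal = order_distribution(_pco_from_values([0.1] * 50 + [0.4] * 50))
    assert mean_profile(bimodal).values[0] == pytest.approx(0.25, abs=0.0051)


def test_mean_profile_within_support():
    rng = np.random.default_rng(8)
    dist = order_distribution(_pco_from_values(rng.uniform(0.0, 0.5, 200)))
    prof = mean_profile(dist)
    occ = dist.bin_centres[dist.histograms[0] > 0]
    assert occ.min() <= prof.values[0] <= occ.max()


def test_hydrogen_free_chain_requires_reconstruction():
    traj, _ = _one_chain_traj([(0, 0, -1)] * 2)
    # united-atom style topology: the two carbons form one hydrogen-free chain
    top = Topology(7, [MoleculeRecord(0, "DPPC", (0, 7), head=0, chains=[
        ChainSpec("sn-1", [1, 4], [[], []]),
        ChainSpec("sn-2", [1, 4], [[], []]),
    ])])
    from memnano.model import TopologyError

    with pytest.raises(TopologyError):
        per_chain_order(traj, top, None, chain=None)
    pco = per_chain_order(traj, top, None, chain=None, reconstruct_hydrogens=True)
    # skeleton along z -> reconstructed C-H bonds lie in-plane -> -S_CD = 0.5
    assert np.allclose(pco.values, 0.5, atol=1e-9)
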