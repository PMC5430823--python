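"""Spatial maps: surfaces, thickness, order, jumps, interleaflet correlation."""

import numpy as np
import pytest

from conftest import region_distance_grid
from memnano.grids import GridMap
from memnano.maps import (
    area_per_lipid,
    interleaflet_histogram,
    jump_map,
    order_map,
    surface_map,
    thickness_map,
)
from memnano.model import Frame, Trajectory
from memnano.order import per_chain_order
from memnano.presets import preset_config
from memnano.synthetic import generate


def test_flat_surfaces_and_thickness(homogeneous_lo):
    traj, top, gt, asg = homogeneous_lo
    up = surface_map(traj, top, asg, "upper", 0.5, 0.5)
    lo = surface_map(traj, top, asg, "lower", 0.5, 0.5)
    assert np.allclose(up.values, 7.1, atol=1e-6)  # midplane 5.0 + offset 2.1
    assert np.allclose(lo.values, 2.9, atol=1e-6)
    thick = thickness_map(traj, top, asg, 0.5, 0.5)
    assert np.allclose(thick.values, 4.2, atol=1e-6)
    # thickness mean equals the difference of the surface means
    assert np.nanmean(thick.values) == pytest.approx(
        np.nanmean(up.values) - np.nanmean(lo.values))


def test_surface_translation_equivariance(homogeneous_lo):
    traj, top, gt, asg = homogeneous_lo
    cell = 0.5
    ref = surface_map(traj, top, asg, "upper", cell, 0.5)
    shifted_frames = [Frame(f.time, f.positions + np.array([cell, 0, 0]), f.box)
                      for f in traj.frames]
    shifted = Trajectory(shifted_frames, dt=traj.dt)
    sm = surface_map(shifted, top, asg, "upper", cell, 0.5)
    assert np.allclose(sm.values, np.roll(ref.values, 1, axis=0), atol=1e-9)


def test_sinusoidal_surface_amplitude_recovery():
    cfg = preset_config("homogeneous-lo", seed=6)
    cfg.ripple_amplitude = 0.5
    cfg.n_frames = 10
    traj, top, _ = generate(cfg)
    from memnano.leaflets import assign_leaflets

    asg = assign_leaflets(traj, top)
    sm = surface_map(traj, top, asg, "upper", 0.5, 0.5)
    amp = 0.5 * (np.nanmax(sm.values) - np.nanmin(sm.values))
    # Gaussian smoothing attenuates a wavelength-8nm ripple by < 10%
    assert amp >= 0.45


def test_thickness_step_recovery(thickness_fixture):
    traj, top, gt, asg = thickness_fixture
    thick = thickness_map(traj, top, asg, 0.5, 0.4)
    d = region_distance_grid(thick)
    assert np.nanmean(thick.values[d < 1.6]) == pytest.approx(4.6, abs=0.05)
    assert np.nanmean(thick.values[(d > 3.3) & (d < 3.7)]) == pytest.approx(4.2, abs=0.05)
    assert np.nanmean(thick.values[d > 5.3]) == pytest.approx(3.8, abs=0.05)


def test_order_map_plateaus(nanodomain, nanodomain_pco):
    traj, top, gt, asg = nanodomain
    om = order_map(nanodomain_pco, traj, top, asg, "upper", 0.5)
    d = region_distance_grid(om)
    assert np.nanmean(om.values[d < 1.6]) == pytest.approx(0.45, abs=0.02)
    assert np.nanmean(om.values[d > 5.3]) == pytest.approx(0.15, abs=0.02)
    # unvisited cells are NaN with zero occupancy
    nan_cells = np.isnan(om.values)
    assert (om.occupancy[nan_cells] == 0).all()


def test_jump_map_static_and_drift():
    # two static frames -> zero everywhere it is defined
    traj, top, _ = generate(preset_config("gel", seed=1))
    from memnano.leaflets import assign_leaflets

    asg = assign_leaflets(traj, top)
    jm = jump_map(traj, top, asg, "upper", window=1.0, grid_cell=1.0)
    assert np.nanmax(jm.values) == pytest.approx(0.0, abs=1e-12)


def test_jump_map_frozen_core_mobile_background(nanodomain):
    traj, top, gt, asg = nanodomain
    jm = jump_map(traj, top, asg, "upper", window=1.0, grid_cell=1.0)
    d = region_distance_grid(jm)
    core = np.nanmean(jm.values[d < 2.0])
    background = np.nanmean(jm.values[d > 5.0])
    assert core == pytest.approx(0.0, abs=1e-9)
    # 2D random walk, 10 steps of sigma=0.06/frame: E|d| = sigma*sqrt(n*pi/2)
    expected = 0.06 * np.sqrt(10 * np.pi / 2)
    assert background == pytest.approx(expected, rel=0.25)


def test_jump_map_time_reversal_invariance(nanodomain):
    traj, top, gt, asg = nanodomain
    ref = jump_map(traj, top, asg, "upper", window=1.0, grid_cell=1.0)
    n = traj.n_frames
    rev = Trajectory([Frame(traj.frames[n - 1 - k].time * -1 + traj.times[-1],
                            traj.frames[n - 1 - k].positions,
                            traj.frames[n - 1 - k].box) for k in range(n)],
                     dt=traj.dt)
    # displacement magnitudes are symmetric; binning cell differs (start vs end
    # of each window), so compare the global means
    jm = jump_map(rev, top, asg, "upper", window=1.0, grid_cell=1.0)
    assert np.nanmean(jm.values) == pytest.approx(np.nanmean(ref.values), rel=0.1)


def test_interleaflet_registration(nanodomain, nanodomain_pco):
    traj, top, gt, asg = nanodomain
    up = order_map(nanodomain_pco, traj, top, asg, "upper", 0.5)
    lo = order_map(nanodomain_pco, traj, top, asg, "lower", 0.5)
    joint = interleaflet_histogram(up, lo)
    assert joint.pearson_r >= 0.9
    assert joint.diagonal_band_mass >= 0.8
    assert joint.hist.sum() == pytest.approx(1.0, abs=1e-9)


def test_interleaflet_antiregistration(nanodomain_anti):
    traj, top, gt, asg = nanodomain_anti
    pco = per_chain_order(traj, top, asg, chain="sn-2")
    up = order_map(pco, traj, top, asg, "upper", 0.5)
    lo = order_map(pco, traj, top, asg, "lower", 0.5)
    joint = interleaflet_histogram(up, lo)
    assert joint.pearson_r <= -0.9


def test_homogeneous_joint_histogram_compact(homogeneous_lo):
    traj, top, gt, asg = homogeneous_lo
    pco = per_chain_order(traj, top, asg, chain="sn-2")
    up = order_map(pco, traj, top, asg, "upper", 0.5)
    lo = order_map(pco, traj, top, asg, "lower", 0.5)
    # bins on the standard order scale, not zoomed into the noise floor
    joint = interleaflet_histogram(up, lo, bins=np.linspace(-0.1, 0.55, 21))
    # a homogeneous phase shows one localized mode: the cells within 2 bins of
    # the peak hold nearly all the mass
    i, j = np.unravel_index(np.argmax(joint.hist), joint.hist.shape)
    window = joint.hist[max(i - 2, 0):i + 3, max(j - 2, 0):j + 3]
    assert window.sum() > 0.9


def test_grid_mismatch_rejected(homogeneous_lo, nanodomain, nanodomain_pco):
    traj, top, gt, asg = nanodomain
    up = order_map(nanodomain_pco, traj, top, asg, "upper", 0.5)
    small = order_map(nanodomain_pco, traj, top, asg, "lower", 1.0)
    with pytest.raises(ValueError, match="grid"):
        interleaflet_histogram(up, small)


def test_area_per_lipid_arithmetic():
    from memnano.model import ChainSpec, LeafletAssignment, MoleculeRecord, Topology

    n = 512
    mols = [MoleculeRecord(i, "DPPC", (i, i + 1), head=i, chains=[
        ChainSpec("sn-1", [i], [[i]]), ChainSpec("sn-2", [i], [[i]])])
        for i in range(n)]
    top = Topology(n, mols)
    labels = np.ones((1, n), dtype=np.int8)
    asg = LeafletAssignment(labels, labels[0],
                            GridMap(np.zeros((2, 2)), np.zeros((2, 2)), 9.0,
                                    (18.0, 18.0)))
    apl = area_per_lipid((18.0, 18.0, 10.0), top, asg, "upper")
    assert apl == pytest.approx(18.0 * 18.0 / 512)
    assert area_per_lipid((36.0, 18.0, 10.0), top, asg, "upper") == pytest.approx(2 * apl)


def test_area_per_lipid_cholesterol_rule(homogeneous_lo):
    traj, top, gt, asg = homogeneous_lo
    n_all = sum(1 for k in asg.molecules_in("upper"))
    n_chol = sum(1 for k in asg.molecules_in("upper") if top.molecules[k].is_sterol)
    a_with = area_per_lipid(traj.box, top, asg, "upper", count_cholesterol=True)
    a_without = area_per_lipid(traj.box, top, asg, "upper", count_cholesterol=False)
    assert a_with == pytest.approx(traj.box[0] * traj.box[1] / n_all)
    assert a_without == pytest.approx(traj.box[0] * traj.box[1] / (n_all - n_chol))
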