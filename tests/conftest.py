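"""Shared fixtures: synthetic membranes generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from memnano import assign_leaflets, per_chain_order
from memnano.presets import preset_config, thickness_step_config
from memnano.synthetic import generate


@pytest.fixture(scope="session")
def nanodomain():
    """Registered nanodomain membrane: hex core + ordered annulus + background."""
    cfg = preset_config("nanodomain-registered", seed=2)
    traj, top, gt = generate(cfg)
    asg = assign_leaflets(traj, top)
    return traj, top, gt, asg


@pytest.fixture(scope="session")
def nanodomain_anti():
    cfg = preset_config("nanodomain-antiregistered", seed=2)
    traj, top, gt = generate(cfg)
    asg = assign_leaflets(traj, top)
    return traj, top, gt, asg


@pytest.fixture(scope="session")
def nanodomain_pco(nanodomain):
    traj, top, gt, asg = nanodomain
    return per_chain_order(traj, top, asg, chain="sn-2")


@pytest.fixture(scope="session")
def thickness_fixture():
    """Uniform-packing three-level (3.8/4.2/4.6 nm) membrane."""
    cfg = thickness_step_config(seed=5)
    traj, top, gt = generate(cfg)
    asg = assign_leaflets(traj, top)
    return traj, top, gt, asg


@pytest.fixture(scope="session")
def flip_fixture():
    cfg = preset_config("flipflop-script", seed=9)
    traj, top, gt = generate(cfg)
    asg = assign_leaflets(traj, top)
    return traj, top, gt, asg


@pytest.fixture(scope="session")
def homogeneous_lo():
    cfg = preset_config("homogeneous-lo", seed=4)
    traj, top, gt = generate(cfg)
    asg = assign_leaflets(traj, top)
    return traj, top, gt, asg


def region_distance_grid(gm, centre=(6.0, 6.0), box=12.0):
    """Periodic distance of each cell centre from a disc centre (test helper)."""
    xs, ys = gm.cell_centres()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    dx = np.minimum(np.abs(gx - centre[0]), box - np.abs(gx - centre[0]))
    dy = np.minimum(np.abs(gy - centre[1]), box - np.abs(gy - centre[1]))
    return np.sqrt(dx ** 2 + dy ** 2)
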