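"""Packing analyses: RDF, neighbour counts, thickness occupancy, tilt, faces."""

import numpy as np
import pytest
from scipy import stats

from conftest import region_distance_grid
from memnano.grids import GridMap
from memnano.maps import thickness_map
from memnano.model import ChainSpec, Frame, GeometryError, MoleculeRecord, Topology
from memnano.packing import (
    chain_sites,
    collective_tilt,
    face_orientation_preference,
    neighbor_counts,
    rdf_2d,
    thickness_occupancy,
)


def _hex_lattice(a, nx, ny):
    pts = []
    for r in range(ny):
        for c in range(nx):
            pts.append(((c + 0.5 * (r % 2)) * a, r * a * np.sqrt(3) / 2))
    return np.array(pts)


def hex_box(a, nx, ny):
    # periodic-commensurate box for an nx x ny hexagonal lattice
    return (nx * a, ny * a * np.sqrt(3) / 2)


def test_chain_sites_counts(homogeneous_lo):
    traj, top, gt, asg = homogeneous_lo
    n_dppc = sum(1 for k in asg.molecules_in("upper")
                 if top.molecules[k].species == "DPPC")
    n_chol = sum(1 for k in asg.molecules_in("upper")
                 if top.molecules[k].is_sterol)
    s0 = chain_sites(traj.frames[0], top, asg, "upper", False, 0)
    s1 = chain_sites(traj.frames[0], top, asg, "upper", True, 0)
    assert s0.shape[0] == 2 * n_dppc
    assert s1.shape[0] == 2 * n_dppc + n_chol
    assert n_chol > 0


def test_rdf_ideal_gas_is_flat():
    rng = np.random.default_rng(0)
    sites = rng.uniform(0, 20, (10_000, 2))
    r, g, _ = rdf_2d(sites, (20.0, 20.0), dr=0.05, r_max=3.0)
    far = g[r > 1.0]
    assert np.abs(far - 1.0).max() < 0.05


def test_rdf_hexagonal_lattice_peak_and_minimum():
    a = 0.5
    rng = np.random.default_rng(4)
    # a whisker of jitter keeps lattice shells off exact bin edges
    sites = _hex_lattice(a, 24, 24) + rng.normal(0, 0.005, (576, 2))
    box = hex_box(a, 24, 24)
    r, g, rmin = rdf_2d(sites, box, dr=0.02, r_max=1.5)
    first_peak = r[np.argmax(g)]
    assert first_peak == pytest.approx(a, abs=0.03)
    assert a < rmin < a * np.sqrt(3)


def test_rdf_invalid_dr():
    with pytest.raises(ValueError):
        rdf_2d(np.zeros((3, 2)), (5, 5), dr=0.0)


def test_neighbor_counts_hexagonal_and_cutoff_independence():
    a = 0.5
    sites = _hex_lattice(a, 20, 20)
    box = hex_box(a, 20, 20)
    for cutoff in (a * 1.1, a * 1.4, a * np.sqrt(3) * 0.98):
        nh = neighbor_counts(sites, box, cutoff)
        assert nh.counts[6] == nh.n_sites  # periodic lattice: every site has 6


def test_neighbor_counts_square_lattice():
    a = 0.5
    xs, ys = np.meshgrid(np.arange(16) * a, np.arange(16) * a)
    sites = np.column_stack([xs.ravel(), ys.ravel()])
    nh = neighbor_counts(sites, (16 * a, 16 * a), a * 1.2)
    assert nh.counts[4] == nh.n_sites


def test_neighbor_counts_translation_and_relabel_invariance():
    rng = np.random.default_rng(1)
    sites = rng.uniform(0, 10, (200, 2))
    box = (10.0, 10.0)
    ref = neighbor_counts(sites, box, 0.8).counts
    shifted = neighbor_counts(sites + [3.7, -1.2], box, 0.8).counts
    perm = neighbor_counts(sites[rng.permutation(200)], box, 0.8).counts
    assert np.array_equal(ref, shifted)
    assert np.array_equal(ref, perm)


def test_nanodomain_core_six_neighbors(nanodomain):
    traj, top, gt, asg = nanodomain
    from scipy.spatial import cKDTree

    sites = chain_sites(traj.frames[0], top, asg, "upper", False, 0)
    _, _, rmin = rdf_2d(sites, traj.box[:2], dr=0.02, r_max=1.5)
    nh = neighbor_counts(sites, traj.box[:2], rmin)
    core = gt.interior_core_sites("upper")
    tree = cKDTree(np.mod(sites, traj.box[:2]), boxsize=traj.box[:2])
    _, idx = tree.query(np.mod(core, traj.box[:2]))
    assert np.mean(nh.per_site[idx] == 6) >= 0.95
    # background chains sit on a sparser lattice: their modal count is below 6
    bg_sites = [s for m in gt.molecules_where(leaflet="upper", region="disordered",
                                              species="DPPC") for s in m["sites"]]
    _, bg_idx = tree.query(np.mod(np.array(bg_sites), traj.box[:2]))
    bg_counts = np.bincount(nh.per_site[bg_idx])
    assert np.argmax(bg_counts) < 6


def test_thickness_occupancy_annulus_enrichment(nanodomain):
    """Cholesterol sits in the ordered annulus: mass at 4.2 nm, none above 4.45."""
    traj, top, gt, asg = nanodomain
    thick = thickness_map(traj, top, asg, 0.5, 0.4)
    sterol_xy = [np.array([f.positions[m.ring].mean(axis=0)[:2]
                           for m in top.sterols()]) for f in traj.frames]
    occ = thickness_occupancy(thick, sterol_xy)
    centres = 0.5 * (occ.bin_edges[:-1] + occ.bin_edges[1:])
    assert occ.cholesterol_cells[centres > 4.45].sum() == 0.0
    assert occ.cholesterol_cells[(centres > 4.0) & (centres < 4.45)].sum() > 0.3
    # cumulatives are monotone from 0 to 1
    for cum in (occ.cumulative_all, occ.cumulative_chol):
        assert (np.diff(cum) >= -1e-12).all()
        assert cum[-1] == pytest.approx(1.0)
    # enrichment toward thicker cells: below the annulus plateau the
    # cholesterol cumulative lags the all-cell cumulative (stochastic
    # dominance); yet cholesterol is exhausted before the thickest core bins
    sel = centres < 4.1
    assert (occ.cumulative_chol[sel] <= occ.cumulative_all[sel] + 1e-9).all()
    first_core_bin = np.searchsorted(centres, 4.45)
    assert occ.cumulative_chol[first_core_bin] == pytest.approx(1.0)


def test_thickness_occupancy_uniform_null():
    rng = np.random.default_rng(3)
    vals = rng.normal(4.0, 0.2, (24, 24))
    gm = GridMap(vals, np.ones_like(vals), 0.5, (12.0, 12.0))
    xy = [rng.uniform(0, 12, (200, 2)) for _ in range(5)]
    occ = thickness_occupancy(gm, xy)
    # two-sample KS at alpha = 0.01 cannot reject the shared distribution
    assert occ.ks_pvalue > 0.01


def test_thickness_occupancy_no_cholesterol():
    vals = np.full((8, 8), 4.0)
    gm = GridMap(vals, np.ones_like(vals), 0.5, (4.0, 4.0))
    occ = thickness_occupancy(gm, [np.empty((0, 2))])
    assert not occ.has_cholesterol
    assert occ.cholesterol_cells.sum() == 0.0


def _chain_frames(axes, box=(30.0, 30.0, 10.0)):
    """One frame of many 3-carbon chains with prescribed axes (two per DPPC)."""
    n = len(axes)
    assert n % 2 == 0
    pos = []
    mols = []
    idx = 0
    rng = np.random.default_rng(0)
    for m in range(n // 2):
        start = idx
        head_xy = rng.uniform(1, 29, 2)
        pos.append([head_xy[0], head_xy[1], 7.0])
        idx += 1
        chains = []
        for c in range(2):
            axis = np.asarray(axes[2 * m + c], dtype=float)
            axis = axis / np.linalg.norm(axis)
            carbons = []
            for k in range(3):
                pos.append([head_xy[0] + c * 0.5 + axis[0] * 0.127 * k,
                            head_xy[1] + axis[1] * 0.127 * k,
                            6.5 + axis[2] * 0.127 * k])
                carbons.append(idx)
                idx += 1
            chains.append(ChainSpec(f"sn-{c + 1}", carbons, [[], [], []]))
        mols.append(MoleculeRecord(m, "DPPC", (start, idx), head=start, chains=chains))
    top = Topology(idx, mols)
    return [Frame(0.0, np.array(pos), box)], top


def test_collective_tilt_upright():
    frames, top = _chain_frames([(0, 0, -1)] * 10)
    angle, resultant, _ = collective_tilt(frames, top)
    assert angle == pytest.approx(0.0, abs=1e-6)
    assert resultant == pytest.approx(0.0, abs=1e-9)


def test_collective_tilt_coherent_30deg():
    a = np.radians(30)
    frames, top = _chain_frames([(np.sin(a), 0, -np.cos(a))] * 10)
    angle, resultant, direction = collective_tilt(frames, top)
    assert angle == pytest.approx(30.0, abs=1e-6)
    assert resultant == pytest.approx(1.0, abs=1e-9)
    assert abs(direction[0]) == pytest.approx(1.0, abs=1e-9)


def test_collective_tilt_random_azimuth_cancels():
    rng = np.random.default_rng(9)
    a = np.radians(30)
    phis = rng.uniform(0, 2 * np.pi, 1000)
    axes = [(np.sin(a) * np.cos(p), np.sin(a) * np.sin(p), -np.cos(a)) for p in phis]
    frames, top = _chain_frames(axes)
    angle, resultant, _ = collective_tilt(frames, top)
    assert angle == pytest.approx(30.0, abs=0.5)
    assert resultant < 0.1


def test_collective_tilt_empty_region():
    frames, top = _chain_frames([(0, 0, -1)] * 4)
    with pytest.raises(GeometryError):
        collective_tilt(frames, top, region_mask=lambda xy: False)


def test_face_orientation_scripted_preference(nanodomain_faces):
    """Sterols built with the rough face toward the disordered side score 1.0."""
    traj, top, gt, order_gm = nanodomain_faces
    annulus_ids = [m["id"] for m in gt.molecules_where(species="CHOL",
                                                       region="ordered")]
    rep = face_orientation_preference(traj.frames, top, order_gm,
                                      sterol_indices=annulus_ids)
    assert rep["n"] >= 100
    assert rep["fraction_toward_disordered"] == pytest.approx(1.0)
    assert rep["p_value"] < 1e-6


def test_face_orientation_random_null(nanodomain, nanodomain_pco):
    from memnano.maps import order_map

    traj, top, gt, asg = nanodomain
    om = order_map(nanodomain_pco, traj, top, asg, "upper", 0.5)
    rep = face_orientation_preference(traj.frames, top, om)
    n = rep["n"]
    ci = 3.0 / np.sqrt(n)  # ~3 sigma binomial envelope
    assert abs(rep["fraction_toward_disordered"] - 0.5) < max(ci, 0.2)


def test_face_orientation_zero_gradient_flags_no_boundary(homogeneous_lo):
    traj, top, gt, asg = homogeneous_lo
    flat = GridMap(np.full((16, 16), 0.35), np.ones((16, 16)), 0.5, (8.0, 8.0))
    rep = face_orientation_preference(traj.frames[:2], top, flat)
    assert rep["no_boundary"] is True


@pytest.fixture(scope="module")
def nanodomain_faces():
    from memnano.presets import preset_config
    from memnano.synthetic import generate

    cfg = preset_config("nanodomain-registered", seed=13)
    cfg.sterol_face = "toward_disordered"
    cfg.n_frames = 6
    traj, top, gt = generate(cfg)
    # analytic order field decreasing radially from the domain centre: the
    # gradient points inward (toward order) everywhere
    nx = ny = 24
    xs = (np.arange(nx) + 0.5) * 0.5
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    dx = np.minimum(np.abs(gx - 6.0), 12.0 - np.abs(gx - 6.0))
    dy = np.minimum(np.abs(gy - 6.0), 12.0 - np.abs(gy - 6.0))
    vals = 0.45 - 0.04 * np.sqrt(dx ** 2 + dy ** 2)
    om = GridMap(vals, np.ones_like(vals), 0.5, (12.0, 12.0))
    return traj, top, gt, om
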