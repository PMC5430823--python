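"""Flip-flop detection (hysteresis + dwell) and boundary enrichment."""

import numpy as np
import pytest

from memnano.flipflop import (
    detect_all_flipflops,
    detect_flipflops,
    flipflop_boundary_enrichment,
    leaflet_trace,
)
from memnano.grids import GridMap
from memnano.leaflets import SamplingError, assign_leaflets
from memnano.presets import preset_config
from memnano.regions import classify
from memnano.synthetic import generate


def _times(n, dt=0.1):
    return np.arange(n) * dt


def test_leaflet_trace_constant(homogeneous_lo):
    traj, top, gt, asg = homogeneous_lo
    k = next(i for i, m in enumerate(top.molecules) if m.is_sterol
             and asg.static_labels[i] == 1)
    trace = leaflet_trace(traj, top, asg, k)
    drift = traj.positions_array()[:, top.molecules[k].ring, 2].mean(axis=1) - 5.0
    assert np.allclose(trace, drift, atol=0.05)
    assert (trace > 0).all()


def test_leaflet_trace_rippled_midplane():
    cfg = preset_config("homogeneous-lo", seed=8)
    cfg.ripple_amplitude = 0.6
    cfg.n_frames = 5
    traj, top, gt = generate(cfg)
    asg = assign_leaflets(traj, top)
    for k, m in enumerate(top.molecules):
        if m.is_sterol and asg.static_labels[k] == 1:
            trace = leaflet_trace(traj, top, asg, k)
            assert (trace > 0).all()  # follows the upper surface over ripples


def test_single_crossing_single_event():
    t = _times(100)
    trace = np.where(t < 5.0, 0.8, -0.8)
    ev = detect_flipflops(trace, t, delta=0.4, tau_min=1.0)
    assert len(ev) == 1
    assert ev[0].direction == "upper->lower"
    assert ev[0].time == pytest.approx(5.0, abs=0.11)


def test_subthreshold_oscillation_ignored():
    t = _times(200)
    trace = 0.3 * np.sin(2 * np.pi * t / 3.0)
    assert detect_flipflops(trace, t, delta=0.4, tau_min=1.0) == []


def _scripted_trace(n=200, dt=0.1, crossings=(2, 4.5, 7, 9.5, 12, 14.5, 17),
                    feints=(3.2, 8.2, 15.7)):
    t = _times(n, dt)
    z = np.empty(n)
    side = 1.0
    ci = list(crossings)
    for i, ti in enumerate(t):
        while ci and ti >= ci[0]:
            side = -side
            ci.pop(0)
        z[i] = 0.8 * side
    for tf in feints:
        mask = np.abs(t - tf) < 0.15
        z[mask] -= np.sign(z[mask]) * 0.55
    return t, z


def test_scripted_crossings_with_feints():
    t, z = _scripted_trace()
    ev = detect_flipflops(z, t, delta=0.4, tau_min=1.0)
    assert len(ev) == 7
    dirs = [e.direction for e in ev]
    assert all(a != b for a, b in zip(dirs, dirs[1:]))
    assert np.allclose([e.time for e in ev], [2, 4.5, 7, 9.5, 12, 14.5, 17], atol=0.11)


def test_noise_below_half_delta_does_not_change_events():
    t, z = _scripted_trace()
    ref = [e.time for e in detect_flipflops(z, t, delta=0.4, tau_min=1.0)]
    rng = np.random.default_rng(0)
    noisy = z + rng.uniform(-0.19, 0.19, z.shape)
    ev = detect_flipflops(noisy, t, delta=0.4, tau_min=1.0)
    assert len(ev) == len(ref)
    assert np.allclose([e.time for e in ev], ref, atol=0.3)


@pytest.mark.parametrize("param", ["delta", "tau_min"])
def test_event_count_monotone(param):
    t, z = _scripted_trace()
    rng = np.random.default_rng(1)
    z = z + rng.normal(0, 0.05, z.shape)
    values = np.linspace(0.1, 0.75, 6) if param == "delta" else [0.0, 0.5, 1.0, 2.0, 2.4]
    counts = []
    for v in values:
        kw = {"delta": 0.4, "tau_min": 1.0}
        kw[param] = v
        counts.append(len(detect_flipflops(z, t, **kw)))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_short_trace_rejected():
    with pytest.raises(SamplingError):
        detect_flipflops(np.array([0.8, -0.8]), np.array([0.0, 0.1]),
                         delta=0.4, tau_min=1.0)


def test_fixture_events_match_script(flip_fixture):
    traj, top, gt, asg = flip_fixture
    events = detect_all_flipflops(traj, top, asg, delta=0.4, tau_min=1.0)
    assert len(events) == len(gt.flip_events) == 7
    for ev, want in zip(events, gt.flip_events):
        assert ev.molecule_id == want["molecule_id"]
        assert ev.direction == want["direction"]
        assert ev.time == pytest.approx(want["time"], abs=0.25)


def _half_plane_region():
    """Straight-band domain: boundary is exactly 4 of 20 columns (20% area)."""
    vals = np.full((20, 20), 3.8)
    vals[:10, :] = 4.6
    gm = GridMap(vals, np.ones_like(vals), 0.5, (10.0, 10.0))
    return classify(gm, (4.0, 4.4), min_domain_cells=1)


def test_boundary_enrichment_scripted():
    rm = _half_plane_region()
    assert rm.boundary.sum() == 80  # 4 columns of 20
    ii, jj = np.nonzero(rm.boundary)
    cell = rm.cell_size
    events = []
    from memnano.flipflop import FlipFlopEvent

    for k in range(20):
        events.append(FlipFlopEvent(k, 1.0 * k, "upper->lower",
                                    ((ii[k] + 0.5) * cell, (jj[k] + 0.5) * cell)))
    rep = flipflop_boundary_enrichment(events, rm, shell_width=0.05)
    assert rep["shell_area_fraction"] == pytest.approx(0.2)
    assert rep["enrichment_ratio"] == pytest.approx(5.0)
    assert rep["p_value"] < 1e-3


def test_boundary_enrichment_uniform_null():
    rm = _half_plane_region()
    rng = np.random.default_rng(7)
    from memnano.flipflop import FlipFlopEvent

    ratios = []
    for rep_i in range(20):
        events = [FlipFlopEvent(k, 0.0, "upper->lower", tuple(rng.uniform(0, 10, 2)))
                  for k in range(200)]
        rep = flipflop_boundary_enrichment(events, rm, shell_width=0.05)
        ratios.append(rep["enrichment_ratio"])
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


def test_zero_events_rejected():
    rm = _half_plane_region()
    with pytest.raises(ValueError):
        flipflop_boundary_enrichment([], rm, shell_width=0.5)


def test_empty_boundary_rejected():
    gm = GridMap(np.full((8, 8), 4.0), np.ones((8, 8)), 0.5, (4.0, 4.0))
    rm = classify(gm, (3.5, 4.5))
    from memnano.flipflop import FlipFlopEvent

    with pytest.raises(ValueError):
        flipflop_boundary_enrichment(
            [FlipFlopEvent(0, 0.0, "upper->lower", (1.0, 1.0))], rm, 0.5)
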