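"""Named synthetic-membrane presets.

Each preset is a complete :class:`SyntheticConfig` describing one study
condition: homogeneous single-phase membranes for reference order
distributions, a nanodomain membrane (hexagonally packed cholesterol-poor
core + ordered cholesterol-rich annulus + disordered background) in
registered and antiregistered variants, a shrinking-domain scenario, and a
scripted flip-flop scenario.  Desk-scale sizes: boxes of 8-12 nm and a few
nanoseconds, which keep every analysis verifiable in seconds while preserving
the statistical structure the analyses detect.
"""

from __future__ import annotations

from .synthetic import RegionSpec, SyntheticConfig

#: region parameter sets: (S_target, phosphate |z| nm, lattice constant nm,
#: site jitter nm, cholesterol mole fraction, step sigma nm/frame, S spread)
_DISORDERED = dict(s_target=0.15, thickness_offset=1.9, lattice_constant=0.62,
                   jitter_sigma=0.03, chol_fraction=0.05, sigma_step=0.06,
                   s_sigma=0.02, packing="jittered")
_ORDERED = dict(s_target=0.35, thickness_offset=2.1, lattice_constant=0.57,
                jitter_sigma=0.02, chol_fraction=0.25, sigma_step=0.02,
                s_sigma=0.02, packing="jittered")
_CORE = dict(s_target=0.45, thickness_offset=2.3, lattice_constant=0.49,
             jitter_sigma=0.008, chol_fraction=0.0, sigma_step=0.0,
             s_sigma=0.015, packing="hexagonal")

PRESET_NAMES = (
    "homogeneous-ld",
    "homogeneous-lo",
    "gel",
    "nanodomain-registered",
    "nanodomain-antiregistered",
    "shrinking-domain",
    "flipflop-script",
)


def _homogeneous(params: dict, label: str, seed: int, box=8.0,
                 n_frames=30) -> SyntheticConfig:
    region = RegionSpec(label=label, geometry="background", **params)
    mirror = RegionSpec(label=label, geometry="background", **params)
    return SyntheticConfig(
        box=(box, box, 10.0),
        regions_upper=[region], regions_lower=[mirror],
        registration="registered", n_frames=n_frames, dt=0.1, seed=seed,
    )


def _nanodomain_regions(anti: bool) -> tuple[list[RegionSpec], list[RegionSpec]]:
    centre = (6.0, 6.0)
    upper = [
        RegionSpec(label="core", geometry=("disc", centre, 2.5), **_CORE),
        RegionSpec(label="ordered", geometry=("disc", centre, 4.5), **_ORDERED),
        RegionSpec(label="disordered", geometry="background", **_DISORDERED),
    ]
    if not anti:
        lower = [
            RegionSpec(label="core", geometry=("disc", centre, 2.5), **_CORE),
            RegionSpec(label="ordered", geometry=("disc", centre, 4.5), **_ORDERED),
            RegionSpec(label="disordered", geometry="background", **_DISORDERED),
        ]
    else:
        # same geometry, complementary order: lower-leaflet order = 0.6 - upper
        def flip(params, s):
            p = dict(params)
            p["s_target"] = s
            return p

        lower = [
            RegionSpec(label="core", geometry=("disc", centre, 2.5),
                       **flip(_CORE, 0.15)),
            RegionSpec(label="ordered", geometry=("disc", centre, 4.5),
                       **flip(_ORDERED, 0.25)),
            RegionSpec(label="disordered", geometry="background",
                       **flip(_DISORDERED, 0.45)),
        ]
    return upper, lower


def preset_config(name: str, seed: int = 0) -> SyntheticConfig:
    """Build the SyntheticConfig for a named preset."""
    if name == "homogeneous-ld":
        return _homogeneous(_DISORDERED, "disordered", seed)
    if name == "homogeneous-lo":
        return _homogeneous(_ORDERED, "ordered", seed)
    if name == "gel":
        return _homogeneous(_CORE, "core", seed)
    if name in ("nanodomain-registered", "nanodomain-antiregistered"):
        anti = name.endswith("antiregistered")
        upper, lower = _nanodomain_regions(anti)
        return SyntheticConfig(
            box=(12.0, 12.0, 10.0),
            regions_upper=upper, regions_lower=lower,
            registration="antiregistered" if anti else "registered",
            n_frames=30, dt=0.1, seed=seed,
        )
    if name == "shrinking-domain":
        # uniform site density across regions: the tracked quantity is the
        # thickness footprint, which must not be confounded by packing density
        core = dict(_CORE, packing="jittered", lattice_constant=0.57,
                    jitter_sigma=0.02)
        bg = dict(_DISORDERED, lattice_constant=0.57, jitter_sigma=0.02,
                  sigma_step=0.04)

        def mk():
            return [
                RegionSpec(label="core", geometry=("disc", (6.0, 6.0), 3.5), **core),
                RegionSpec(label="disordered", geometry="background", **bg),
            ]

        upper, lower = mk(), mk()
        return SyntheticConfig(
            box=(12.0, 12.0, 10.0),
            regions_upper=upper, regions_lower=lower,
            registration="registered", n_frames=24, dt=0.2, seed=seed,
            shrink={"label": "core", "T": 4.45},
        )
    if name == "flipflop-script":
        ordered = dict(_ORDERED)
        ordered["chol_fraction"] = 0.10
        ordered["sigma_step"] = 0.0
        upper = [RegionSpec(label="ordered", geometry="background", **ordered)]
        lower = [RegionSpec(label="ordered", geometry="background", **ordered)]
        return SyntheticConfig(
            box=(8.0, 8.0, 10.0),
            regions_upper=upper, regions_lower=lower,
            registration="registered", n_frames=200, dt=0.1, seed=seed,
            flip_events=[(0, 2.0), (0, 4.5), (0, 7.0), (0, 9.5),
                         (0, 12.0), (0, 14.5), (0, 17.0)],
            feints=[(0, 3.2, 0.5), (0, 8.2, 0.5), (0, 15.7, 0.5)],
        )
    raise ValueError(f"unknown preset {name!r}; known presets: {', '.join(PRESET_NAMES)}")


def thickness_step_config(seed: int = 0) -> SyntheticConfig:
    """Three-level thickness fixture (3.8 / 4.2 / 4.6 nm) with uniform packing.

    All regions share the same lattice so the smoothed surfaces recover the
    plateau heights and step positions without density-weighting bias; used to
    verify thickness-map and region-area recovery.
    """
    flat = dict(packing="jittered", lattice_constant=0.57, jitter_sigma=0.02,
                chol_fraction=0.0, sigma_step=0.0, s_sigma=0.0)
    centre = (6.0, 6.0)

    def mk():
        return [
            RegionSpec(label="core", geometry=("disc", centre, 2.5),
                       s_target=0.45, thickness_offset=2.3, **flat),
            RegionSpec(label="ordered", geometry=("disc", centre, 4.5),
                       s_target=0.35, thickness_offset=2.1, **flat),
            RegionSpec(label="disordered", geometry="background",
                       s_target=0.15, thickness_offset=1.9, **flat),
        ]

    return SyntheticConfig(
        box=(12.0, 12.0, 10.0),
        regions_upper=mk(), regions_lower=mk(),
        registration="registered", n_frames=10, dt=0.1, seed=seed,
    )
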