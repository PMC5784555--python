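"""Bundled scenario presets: the calibrated silver systems.

Two particle systems (20 nm and 110 nm primary silver cores, protein-coated
in RPMI + 10% FBS) at the two exposure concentrations each that were run
against cell-uptake data. Every number is a measured or calibrated system
parameter; the kinetic constants are the package defaults.
"""

from __future__ import annotations

from dataclasses import replace

from .config import (
    GridSpec,
    InitialDistribution,
    MediaSpec,
    ParticleSpec,
    SystemConfig,
)

__all__ = ["preset", "preset_names", "PRESETS"]


def _silver_system(Dp1, dRc, rho_pc, C0) -> SystemConfig:
    return SystemConfig(
        media=MediaSpec(
            L=0.00315, V=3.0, T=310.0, mu=7.4e-4, rho_f=1.0, A=9.52e-4, P0=10.0
        ),
        particle=ParticleSpec(
            Dp1=Dp1, rho_p1=10.0, state="protein_coated", dRc=dRc,
            rho_pc=rho_pc, Dmin=10.0, C0=C0,
        ),
        grid=GridSpec(dx=3.1532e-6, dDp=1.0, t_max=24.0),
        init=InitialDistribution(kind="delta"),
    )


PRESETS = {
    "ag20_1": _silver_system(20.0, 12.0, 1.583, 1.0),
    "ag20_12.5": _silver_system(20.0, 12.0, 1.583, 12.5),
    "ag110_0.7": _silver_system(110.0, 22.5, 1.914, 0.7),
    "ag110_9.15": _silver_system(110.0, 22.5, 1.914, 9.15),
}


def preset_names() -> list:
    return sorted(PRESETS)


def preset(name: str, **overrides) -> SystemConfig:
    """Return a fresh copy of a named preset, optionally with top-level
    sections replaced (e.g. ``grid=...``)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}")
    cfg = PRESETS[name]
    cfg = replace(cfg)  # shallow copy; sections are frozen by convention
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg
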