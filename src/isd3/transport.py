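"""Size- and density-dependent transport coefficients.

Brownian diffusivity (Stokes-Einstein), gravitational settling (Stokes law,
or the Sterling form for fractal agglomerates), agglomerate porosity and
effective density, and the Peclet diagnostic Pe = L*V_t/D_diff that
classifies a particle's descent as diffusion- (Pe < 1) or sedimentation-
dominated (Pe > 1).

Elementary coefficient functions take and return SI-per-second values as
stated in their docstrings; :func:`transport_coefficients` assembles the
per-size-bin arrays in the canonical per-hour units used by the solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MediaSpec, ParticleSpec

__all__ = [
    "G_STANDARD",
    "BOLTZMANN",
    "TransportCoefficients",
    "diffusion_coefficient",
    "stokes_velocity",
    "sterling_velocity",
    "agglomerate_porosity",
    "agglomerate_density",
    "porosity_from_density",
    "peclet",
    "transport_coefficients",
]

# CODATA constants; the standard acceleration of gravity
G_STANDARD = 9.80665          # m/s^2
GAS_CONSTANT = 8.31446261815324   # J mol^-1 K^-1
AVOGADRO = 6.02214076e23      # mol^-1
BOLTZMANN = GAS_CONSTANT / AVOGADRO  # J/K


@dataclass
class TransportCoefficients:
    """Per-size-bin transport coefficients on the solver grid.

    D_diff and V_t are in the solver's per-hour units (m^2/h, m/h); Pe is
    dimensionless. ``V_t`` may be negative for buoyant particles; the
    solver clamps the bottom flux of such bins to zero by default.
    """

    dp_nodes: np.ndarray   # core diameters, nm
    dpc_nodes: np.ndarray  # transported diameters, nm
    D_diff: np.ndarray     # m^2/h
    V_t: np.ndarray        # m/h
    Pe: np.ndarray         # dimensionless


def diffusion_coefficient(Dpc: float, T: float, mu: float) -> float:
    """Stokes-Einstein diffusivity k_B*T / (3*pi*mu*Dpc) in m^2/s.

    ``Dpc`` is the transported (coated/agglomerate) diameter in nm, ``T``
    in K, ``mu`` in N s/m^2.
    """
    Dpc = np.asarray(Dpc, dtype=float)
    if np.any(Dpc <= 0):
        raise ValueError("diameter must be strictly positive")
    d_m = Dpc * 1e-9
    out = BOLTZMANN * T / (3.0 * np.pi * mu * d_m)
    return out if out.ndim else float(out)


def stokes_velocity(Dpc: float, rho_pc: float, rho_f: float, mu: float) -> float:
    """Stokes settling velocity g*(rho_pc - rho_f)*Dpc^2 / (18*mu) in m/s.

    Densities in g/cm^3 (g/mL), diameter in nm. Negative for buoyant
    particles (rho_pc < rho_f).
    """
    Dpc = np.asarray(Dpc, dtype=float)
    if np.any(Dpc <= 0):
        raise ValueError("diameter must be strictly positive")
    d_m = Dpc * 1e-9
    drho = (rho_pc - rho_f) * 1e3  # g/cm^3 -> kg/m^3
    out = G_STANDARD * drho * d_m ** 2 / (18.0 * mu)
    return out if out.ndim else float(out)


def sterling_velocity(
    Dp: float, Dp1: float, DF: float, rho_p: float, rho_f: float, mu: float
) -> float:
    """Settling velocity of a fractal agglomerate, m/s.

    g*(rho_p - rho_f)*Dp^(DF-1)*Dp1^(3-DF) / (18*mu); reduces to the Stokes
    form at DF = 3 or Dp = Dp1.
    """
    Dp = np.asarray(Dp, dtype=float)
    if np.any(Dp < Dp1):
        raise ValueError("agglomerate diameter cannot be below the primary diameter")
    if not (1.0 < DF <= 3.0):
        raise ValueError("fractal dimension must lie in (1, 3]")
    d_m = Dp * 1e-9
    d1_m = Dp1 * 1e-9
    drho = (rho_p - rho_f) * 1e3
    out = G_STANDARD * drho * d_m ** (DF - 1.0) * d1_m ** (3.0 - DF) / (18.0 * mu)
    return out if out.ndim else float(out)


def agglomerate_porosity(Dp: float, Dp1: float, DF: float) -> float:
    """Porosity eps = 1 - (Dp/Dp1)^(DF-3) of a fractal agglomerate."""
    Dp = np.asarray(Dp, dtype=float)
    if np.any(Dp < Dp1):
        raise ValueError("agglomerate diameter cannot be below the primary diameter")
    out = 1.0 - (Dp / Dp1) ** (DF - 3.0)
    return out if out.ndim else float(out)


def agglomerate_density(eps: float, rho_p1: float, rho_f: float) -> float:
    """Effective density (1 - eps)*rho_p1 + eps*rho_f, g/cm^3."""
    eps = np.asarray(eps, dtype=float)
    if np.any(eps < 0) or np.any(eps > 1):
        raise ValueError("porosity must lie in [0, 1]")
    out = (1.0 - eps) * rho_p1 + eps * rho_f
    return out if out.ndim else float(out)


def porosity_from_density(rho_p: float, rho_p1: float, rho_f: float) -> float:
    """Inverse of :func:`agglomerate_density`: recover eps from a measured
    effective density."""
    eps = (rho_p1 - rho_p) / (rho_p1 - rho_f)
    if not (0.0 <= eps <= 1.0):
        raise ValueError("measured density outside the [rho_f, rho_p1] envelope")
    return float(eps)


def peclet(Dpc: float, rho_pc: float, media: MediaSpec) -> float:
    """Peclet number L * V_t / D_diff for the transported entity."""
    vt = stokes_velocity(Dpc, rho_pc, media.rho_f, media.mu)
    dd = diffusion_coefficient(Dpc, media.T, media.mu)
    out = media.L * np.asarray(vt) / np.asarray(dd)
    return out if out.ndim else float(out)


def transport_coefficients(
    particle: ParticleSpec, media: MediaSpec, dp_nodes: np.ndarray
) -> TransportCoefficients:
    """Assemble per-bin coefficients on the core-diameter grid (per-hour units).

    Protein-coated particles are transported at Dpc = Dp + 2*dRc with the
    measured effective density; agglomerates use the Sterling velocity with
    the porosity-derived density at each size; bare primaries use the core
    values.
    """
    dp_nodes = np.asarray(dp_nodes, dtype=float)
    dpc = np.asarray(particle.effective_diameter(dp_nodes), dtype=float)

    if particle.state == "agglomerate":
        eps = agglomerate_porosity(
            np.maximum(dp_nodes, particle.Dp1), particle.Dp1, particle.DF
        )
        rho = agglomerate_density(eps, particle.rho_p1, media.rho_f)
        vt = np.where(
            dp_nodes > particle.Dp1,
            sterling_velocity(
                np.maximum(dp_nodes, particle.Dp1), particle.Dp1, particle.DF,
                rho, media.rho_f, media.mu,
            ),
            stokes_velocity(dp_nodes, particle.rho_p1, media.rho_f, media.mu),
        )
        dd = diffusion_coefficient(dp_nodes, media.T, media.mu)
    else:
        rho_eff = particle.rho_pc if particle.state == "protein_coated" else particle.rho_p1
        vt = stokes_velocity(dpc, rho_eff, media.rho_f, media.mu)
        dd = diffusion_coefficient(dpc, media.T, media.mu)

    dd_h = np.asarray(dd) * 3600.0
    vt_h = np.asarray(vt) * 3600.0
    pe = media.L * vt_h / dd_h
    return TransportCoefficients(
        dp_nodes=dp_nodes, dpc_nodes=dpc, D_diff=dd_h, V_t=vt_h, Pe=pe
    )
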