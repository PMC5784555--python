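"""Dissolution kinetics and ion transfer.

Silver leaves the particle surface through three surface-area-limited
channels: to the free-ion pool (rate k_f, capacity C_sat), and to the
protein-bound pool through a slow (k_p, capacity n*P0) and an initially
fast (k_p2, capacity n2*P0) pathway. Free and bound ions also exchange
directly (k_f2p, k_p2f), and cells take up dissolved silver by diffusion
across the membrane bounded by the cell:media partition coefficient.

The module provides the right-hand sides of those kinetic systems, the
particle shrink rate they imply, surface-area accounting over a number
density field, and two well-mixed reference integrators (a cell-free vial
and an ion-only exposure) used for calibration and as solver oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .config import (
    DissolutionParams,
    ParticleSpec,
    SystemConfig,
    UptakeParams,
)

__all__ = [
    "GCM3_TO_UGNM3",
    "IonState",
    "SurfaceAreaAccount",
    "mass_per_particle",
    "area_per_particle",
    "shrink_a_factor",
    "particle_surface_area",
    "ion_rhs_media_only",
    "ion_rhs_with_cells",
    "shrink_rate",
    "simple_dissolution_rhs",
    "WellMixedResult",
    "dissolve_well_mixed",
    "IonOnlyResult",
    "ion_uptake_only",
]

GCM3_TO_UGNM3 = 1e-15  # 1 g/cm^3 = 1e6 ug / 1e21 nm^3


@dataclass
class IonState:
    """Dissolved-silver state, all referenced to the media volume (ug/mL)."""

    C_f: float = 0.0
    C_p: float = 0.0
    C_cell: float = 0.0

    @property
    def C_diss(self) -> float:
        return self.C_f + self.C_p

    def as_array(self) -> np.ndarray:
        return np.array([self.C_f, self.C_p, self.C_cell], dtype=float)

    @classmethod
    def from_array(cls, y) -> "IonState":
        return cls(float(y[0]), float(y[1]), float(y[2]))


@dataclass
class SurfaceAreaAccount:
    """Dissolvable particle surface area (nm^2), total and per grid cell."""

    area_total: float
    per_bin: np.ndarray  # shape (n_x, n_dp), quadrature-weighted


# ---------------------------------------------------------------------------
# Per-particle geometry
# ---------------------------------------------------------------------------


def mass_per_particle(Dp, particle: ParticleSpec):
    """Silver mass of one particle of core diameter ``Dp`` (ug).

    Agglomerates above the primary size carry the porosity-reduced density;
    coated or bare particles carry the primary material density (the corona
    is bookkeeping-free).
    """
    scalar = np.isscalar(Dp) or np.ndim(Dp) == 0
    Dp = np.atleast_1d(np.asarray(Dp, dtype=float))
    rho = np.full_like(Dp, particle.rho_p1 * GCM3_TO_UGNM3)
    if particle.state == "agglomerate":
        from .transport import agglomerate_density, agglomerate_porosity

        big = Dp > particle.Dp1
        if np.any(big):
            eps = agglomerate_porosity(Dp[big], particle.Dp1, particle.DF)
            # voids are counted as silver-free: effective silver density is
            # (1-eps)*rho_p1 (media in the pores carries no particle mass)
            rho[big] = agglomerate_density(eps, particle.rho_p1, 0.0) * GCM3_TO_UGNM3
    out = rho * np.pi / 6.0 * Dp ** 3
    return float(out[0]) if scalar else out


def area_per_particle(Dp, particle: ParticleSpec):
    """Dissolvable surface area A_p of one particle (nm^2).

    Spheres expose pi*Dp^2; an agglomerate exposes the total surface of its
    N_p1 = rho_p*Dp^3/(rho_p1*Dp1^3) primary particles.
    """
    scalar = np.isscalar(Dp) or np.ndim(Dp) == 0
    Dp = np.atleast_1d(np.asarray(Dp, dtype=float))
    out = np.pi * Dp ** 2
    if particle.state == "agglomerate":
        big = Dp > particle.Dp1
        if np.any(big):
            n_p1 = np.atleast_1d(mass_per_particle(Dp[big], particle)) / (
                mass_per_particle(particle.Dp1, particle)
            )
            out[big] = n_p1 * np.pi * particle.Dp1 ** 2
    return float(out[0]) if scalar else out


def shrink_a_factor(Dp, particle: ParticleSpec):
    """Geometry factor in the shrink rate: Dp/Dp1 for agglomerates above the
    primary size, 1 otherwise."""
    Dp = np.asarray(Dp, dtype=float)
    if particle.state == "agglomerate":
        out = np.where(Dp > particle.Dp1, Dp / particle.Dp1, 1.0)
    else:
        out = np.ones_like(Dp)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Surface-area accounting over a density field
# ---------------------------------------------------------------------------


def _trapz_weights(nodes: np.ndarray) -> np.ndarray:
    nodes = np.asarray(nodes, dtype=float)
    if nodes.size == 1:
        return np.ones(1)
    w = np.empty_like(nodes)
    w[1:-1] = 0.5 * (nodes[2:] - nodes[:-2])
    w[0] = 0.5 * (nodes[1] - nodes[0])
    w[-1] = 0.5 * (nodes[-1] - nodes[-2])
    return w


def particle_surface_area(field, particle: ParticleSpec, grid=None) -> SurfaceAreaAccount:
    """Total dissolvable surface area of a number-density field.

    ``field`` exposes ``values`` (n_x, n_dp), ``x_nodes`` (m) and
    ``dp_nodes`` (nm). Bins at or below the dissolution floor hold
    non-dissolving cores and contribute nothing.
    """
    values = np.asarray(field.values, dtype=float)
    if np.any(values < -1e-12 * max(1.0, np.abs(values).max(initial=0.0))):
        raise ValueError("number density field has negative values")
    wx = _trapz_weights(field.x_nodes)
    wd = _trapz_weights(field.dp_nodes)
    a_p = area_per_particle(field.dp_nodes, particle)
    dissolving = field.dp_nodes > particle.Dmin + 1e-12
    per_bin = values * wx[:, None] * (wd * a_p * dissolving)[None, :]
    return SurfaceAreaAccount(area_total=float(per_bin.sum()), per_bin=per_bin)


# ---------------------------------------------------------------------------
# Kinetic right-hand sides
# ---------------------------------------------------------------------------


def ion_rhs_media_only(
    state: IonState,
    area_total: float,
    params: DissolutionParams,
    P0: float,
    V: float,
) -> np.ndarray:
    """d/dt of (C_f, C_p, C_cell) for a cell-free system (C_cell inert).

    Driving terms are signed: a pool above its capacity transfers back
    (no clamping).
    """
    n2 = params.n2(P0)
    drive_f = params.C_sat - state.C_f
    drive_p = params.n * P0 - state.C_p
    drive_p2 = n2 * P0 - state.C_p
    aV = area_total / V
    exch = params.k_f2p * state.C_f * drive_p - params.k_p2f * state.C_p * drive_f
    dCf = params.k_f * aV * drive_f - exch
    dCp = params.k_p * aV * drive_p + params.k_p2 * aV * drive_p2 + exch
    return np.array([dCf, dCp, 0.0])


def uptake_fluxes(
    state: IonState, uptake: UptakeParams, V: float
) -> tuple[float, float]:
    """Per-phase diffusion-limited cell uptake rates (ug/mL/h), positive into
    the cells."""
    equil = (state.C_cell * V / uptake.V_cell) / uptake.PC21
    k = uptake.D12 * uptake.SA2 / (V * uptake.Dis2)
    return k * (state.C_f - equil), k * (state.C_p - equil)


def ion_rhs_with_cells(
    state: IonState,
    area_total: float,
    params: DissolutionParams,
    uptake: UptakeParams,
    P0: float,
    V: float,
) -> np.ndarray:
    """Full media + cell ion kinetics with a mass-conserving closure.

    Media phases lose their per-phase uptake fluxes; the cell pool gains
    exactly their sum, so V*(C_f + C_p + C_cell) changes only through the
    particle surface-area terms.
    """
    base = ion_rhs_media_only(state, area_total, params, P0, V)
    u_f, u_p = uptake_fluxes(state, uptake, V)
    return base + np.array([-u_f, -u_p, u_f + u_p])


def shrink_rate(
    Dp,
    state: IonState,
    params: DissolutionParams,
    P0: float,
    particle: ParticleSpec,
):
    """Rate of change of the core diameter due to dissolution, nm/h (<= 0
    under subsaturated media). Zero at or below the dissolution floor.
    """
    Dp = np.asarray(Dp, dtype=float)
    n2 = params.n2(P0)
    k_sum = (
        params.k_f * (params.C_sat - state.C_f)
        + params.k_p * (params.n * P0 - state.C_p)
        + params.k_p2 * (n2 * P0 - state.C_p)
    )  # ug nm^-2 h^-1
    rho = particle.rho_p1 * GCM3_TO_UGNM3  # ug/nm^3
    a = shrink_a_factor(Dp, particle)
    out = np.where(Dp > particle.Dmin + 1e-12, -(2.0 / rho) * a * k_sum, 0.0)
    return out if out.ndim else float(out)


def simple_dissolution_rhs(
    C: float, area_total: float, k_f: float, C_sat: float, V: float
) -> float:
    """One-compartment two-parameter dissolution model (comparison runs)."""
    return k_f * area_total / V * (C_sat - C)


# ---------------------------------------------------------------------------
# Well-mixed cell-free integrator (vial experiments; calibration forward model)
# ---------------------------------------------------------------------------


@dataclass
class WellMixedResult:
    times: np.ndarray        # h
    diameters: np.ndarray    # (n_times, n_classes) core nm
    counts: np.ndarray       # per class (constant; number conserved)
    C_f: np.ndarray
    C_p: np.ndarray
    area: np.ndarray         # nm^2
    particle_mass: np.ndarray  # ug

    @property
    def C_diss(self) -> np.ndarray:
        return self.C_f + self.C_p

    @property
    def mean_diameter(self) -> np.ndarray:
        w = self.counts / self.counts.sum()
        return self.diameters @ w


def _initial_size_classes(cfg: SystemConfig) -> tuple[np.ndarray, np.ndarray]:
    """(diameters, number fractions) of the initial distribution, as discrete
    Lagrangian classes on the configured size spacing."""
    p, init, dDp = cfg.particle, cfg.init, cfg.grid.dDp
    if init.kind == "delta":
        return np.array([init.mean or p.Dp1]), np.array([1.0])
    if init.kind == "gaussian":
        mean = init.mean if init.mean is not None else p.Dp1
        upper = mean + 4.0 * init.sigma
        nodes = np.arange(p.Dp1, upper + 0.5 * dDp, dDp)
        f = np.exp(-((nodes - mean) ** 2) / (2.0 * init.sigma ** 2))
        w = _trapz_weights(nodes) if nodes.size > 1 else np.ones(1)
        frac = f * w
        return nodes, frac / frac.sum()
    # empirical
    d = np.array([row[0] for row in init.table])
    f = np.array([row[1] for row in init.table])
    if np.any(d < p.Dp1 - 1e-9):
        raise ValueError("initial support cannot extend below the primary diameter")
    return d, f / f.sum()


def dissolve_well_mixed(
    cfg: SystemConfig,
    times: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> WellMixedResult:
    """Integrate the cell-free dissolution kinetics in a uniform suspension.

    Particle size classes shrink as Lagrangian characteristics (no size-grid
    discretization error), halting at the dissolution floor; the free and
    protein-bound pools follow the two-compartment kinetics with the
    evolving total surface area. This is the vial-geometry model used to
    calibrate the dissolution parameters.
    """
    p, dparams, media = cfg.particle, cfg.dissolution, cfg.media
    if times is None:
        times = np.linspace(0.0, cfg.grid.t_max, 97)
    times = np.asarray(times, dtype=float)

    d0, frac = _initial_size_classes(cfg)
    m0 = mass_per_particle(d0, p)
    denom = float(np.sum(frac * m0))
    n_total = p.C0 * media.V / denom if denom > 0 else 0.0
    counts = n_total * frac
    shrink_on = cfg.dissolution_enabled

    def rhs(t, y):
        d = y[:-2]
        state = IonState(y[-2], y[-1], 0.0)
        active = d > p.Dmin + 1e-12
        area = float(np.sum(counts * area_per_particle(d, p) * active))
        if not shrink_on:
            return np.zeros_like(y)
        dd = shrink_rate(d, state, dparams, media.P0, p)
        dion = ion_rhs_media_only(state, area, dparams, media.P0, media.V)
        return np.concatenate([np.atleast_1d(dd), dion[:2]])

    y0 = np.concatenate([d0, [0.0, 0.0]])
    sol = solve_ivp(
        rhs, (times[0], times[-1]), y0, t_eval=times, method="LSODA",
        rtol=rtol, atol=atol, max_step=max((times[-1] - times[0]) / 50.0, 1e-3),
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"well-mixed dissolution integration failed: {sol.message}")
    diam = np.clip(sol.y[:-2].T, p.Dmin, None)
    cf, cp = sol.y[-2], sol.y[-1]
    active = diam > p.Dmin + 1e-12
    area = np.einsum(
        "j,tj->t", counts, np.asarray(area_per_particle(diam, p)) * active
    )
    pmass = np.einsum("j,tj->t", counts, np.asarray(mass_per_particle(diam, p)))
    return WellMixedResult(
        times=times, diameters=diam, counts=counts,
        C_f=cf, C_p=cp, area=area, particle_mass=pmass,
    )


# ---------------------------------------------------------------------------
# Ion-only exposure (cell uptake calibration forward model)
# ---------------------------------------------------------------------------


@dataclass
class IonOnlyResult:
    times: np.ndarray
    C_f: np.ndarray
    C_p: np.ndarray
    C_cell: np.ndarray  # referenced to media volume, ug/mL

    @property
    def cell_mass(self) -> np.ndarray:
        """Total ion mass in cells (ug) given the media volume it was run with."""
        return self._V * self.C_cell

    _V: float = 3.0


def ion_uptake_only(
    cfg: SystemConfig,
    C_ion0: float,
    times: Optional[Sequence[float]] = None,
    rtol: float = 1e-9,
) -> IonOnlyResult:
    """Cellular uptake of a pure silver-ion dose (no particles).

    The administered ions start split between the bound and free pools
    according to ``ion_initial_bound_fraction``; the cell pool follows the
    lumped diffusion-limited uptake law on the total dissolved
    concentration, with the media loss apportioned to the two phases by
    their concentration share (mass-conserving).
    """
    dparams, media, upt = cfg.dissolution, cfg.media, cfg.uptake
    if times is None:
        times = np.linspace(0.0, cfg.grid.t_max, 97)
    times = np.asarray(times, dtype=float)
    bf = cfg.ion_initial_bound_fraction

    def rhs(t, y):
        cf, cp, ccell = y
        state = IonState(cf, cp, ccell)
        exch = (
            dparams.k_f2p * cf * (dparams.n * media.P0 - cp)
            - dparams.k_p2f * cp * (dparams.C_sat - cf)
        )
        # lumped uptake law on the total dissolved concentration
        equil = (ccell * media.V / upt.V_cell) / upt.PC21
        flux = (
            upt.D12 * upt.SA2 / (media.V * upt.Dis2) * (cf + cp - equil)
        )
        tot = cf + cp
        share_f = cf / tot if tot > 0 else 0.5
        return [
            -exch - flux * share_f,
            exch - flux * (1.0 - share_f),
            flux,
        ]

    y0 = [C_ion0 * (1.0 - bf), C_ion0 * bf, 0.0]
    sol = solve_ivp(
        rhs, (times[0], times[-1]), y0, t_eval=times, method="LSODA",
        rtol=rtol, atol=1e-13,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"ion uptake integration failed: {sol.message}")
    out = IonOnlyResult(times=times, C_f=sol.y[0], C_p=sol.y[1], C_cell=sol.y[2])
    out._V = media.V
    return out
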