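"""Population-balance solver on the column-depth x particle-size grid.

The number density N(Dp; x, t) (units #/(m nm)) evolves under

* vertical transport — Brownian diffusion and gravitational settling per
  size bin, with zero total flux at the media surface and an absorptive
  (or Robin / no-flux) condition at the cell layer;
* size advection — every bin shrinks at the dissolution rate implied by
  the instantaneous ion state, halting at the dissolution floor where the
  inert cores accumulate;
* ion kinetics — the free / protein-bound / cell pools, fed by the silver
  mass the shrinking particles shed.

Operator splitting per time step: (i) implicit x-transport
(Crank-Nicolson diffusion + upwind advection, backward-Euler startup),
(ii) explicit conservative upwind size advection with CFL sub-cycling,
(iii) an RK4 ion substep whose particle source equals the exact discrete
mass shed in (ii), apportioned across the three kinetic channels by their
driving terms — total silver and total particle number are then conserved
to round-off by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .config import SystemConfig
from .dissolution import (
    IonState,
    _trapz_weights,
    mass_per_particle,
    particle_surface_area,
    shrink_rate,
)
from .transport import transport_coefficients

__all__ = [
    "NumberDensityField",
    "BalanceLedger",
    "SimulationResult",
    "init_number_density",
    "robin_boundary_flux",
    "simulate",
]

_DT_CAP = 0.02        # h, master-step cap (splitting / ion-kinetics accuracy)
_CFL_SAFETY = 0.5


@dataclass
class NumberDensityField:
    """N(Dp; x, t) on the node-centred rectangular grid.

    x runs from 0 (media surface) to L (cell layer); Dp spans the
    dissolution floor up to the top of the initial size support.
    """

    values: np.ndarray   # (n_x, n_dp), #/(m nm)
    x_nodes: np.ndarray  # m
    dp_nodes: np.ndarray  # nm
    time: float = 0.0

    @property
    def x_weights(self) -> np.ndarray:
        return _trapz_weights(self.x_nodes)

    @property
    def dp_weights(self) -> np.ndarray:
        return _trapz_weights(self.dp_nodes)

    def bin_counts(self) -> np.ndarray:
        """Particle count per size bin (x-integrated, quadrature weighted)."""
        return self.dp_weights * (self.x_weights @ self.values)

    def total_count(self) -> float:
        return float(self.bin_counts().sum())

    def total_mass(self, particle) -> float:
        """Total particle silver mass in the media (ug)."""
        return float(self.bin_counts() @ mass_per_particle(self.dp_nodes, particle))


@dataclass
class BalanceLedger:
    """Running audit of silver mass and particle number."""

    rows: list = dc_field(default_factory=list)

    def record(self, t, media_pmass, cell_pmass, media_imass, cell_imass,
               media_count, cell_count):
        self.rows.append(
            dict(
                t_h=t,
                media_particle_ug=media_pmass,
                cell_particle_ug=cell_pmass,
                media_ion_ug=media_imass,
                cell_ion_ug=cell_imass,
                total_silver_ug=media_pmass + cell_pmass + media_imass + cell_imass,
                media_particle_count=media_count,
                cell_particle_count=cell_count,
                total_count=media_count + cell_count,
            )
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def max_relative_drift(self) -> tuple:
        """(mass drift, count drift) relative to the initial totals."""
        df = self.frame()
        m0, n0 = df.total_silver_ug.iloc[0], df.total_count.iloc[0]
        dm = float(np.abs(df.total_silver_ug - m0).max() / m0) if m0 else 0.0
        dn = float(np.abs(df.total_count - n0).max() / n0) if n0 else 0.0
        return dm, dn


@dataclass
class SimulationResult:
    """Time series of every reported observable plus the balance audit."""

    config: SystemConfig
    times: np.ndarray
    media_particle_mass: np.ndarray   # ug
    cell_particle_mass: np.ndarray    # ug
    media_ion_total: np.ndarray       # ug, V*(C_f + C_p)
    cell_ion_mass: np.ndarray         # ug, V*C_cell
    C_f: np.ndarray                   # ug/mL
    C_p: np.ndarray                   # ug/mL
    area_series: np.ndarray           # nm^2
    media_count: np.ndarray
    cell_count: np.ndarray
    cell_size_distribution: np.ndarray  # (n_t, n_dp) cumulative deposit counts
    dp_nodes: np.ndarray
    final_field: NumberDensityField
    ledger: BalanceLedger
    snapshots: Optional[list] = None  # [(t, values)] when requested

    @property
    def C_diss(self) -> np.ndarray:
        return self.C_f + self.C_p

    @property
    def administered_mass(self) -> float:
        return self.config.particle.C0 * self.config.media.V

    @property
    def deposited_fraction(self) -> np.ndarray:
        """Cell-associated silver (particles + ions) over administered silver."""
        tot = self.administered_mass
        if tot == 0:
            return np.zeros_like(self.times)
        return (self.cell_particle_mass + self.cell_ion_mass) / tot

    @property
    def cell_total_silver(self) -> np.ndarray:
        return self.cell_particle_mass + self.cell_ion_mass


# ---------------------------------------------------------------------------
# Grids and initial condition
# ---------------------------------------------------------------------------


def _x_grid(cfg: SystemConfig) -> np.ndarray:
    L, dx = cfg.media.L, cfg.grid.dx
    n = max(2, int(round(L / dx)))
    return np.linspace(0.0, L, n + 1)


def _dp_grid(cfg: SystemConfig) -> np.ndarray:
    p, init, dDp = cfg.particle, cfg.init, cfg.grid.dDp
    if init.kind == "delta":
        upper = init.mean if init.mean is not None else p.Dp1
    elif init.kind == "gaussian":
        mean = init.mean if init.mean is not None else p.Dp1
        upper = mean + 4.0 * init.sigma
    else:
        upper = max(d for d, _ in init.table)
    n = max(1, int(math.ceil((upper - p.Dmin) / dDp - 1e-9)))
    return p.Dmin + dDp * np.arange(n + 1)


def init_number_density(cfg: SystemConfig) -> NumberDensityField:
    """Initial field: size distribution (delta / truncated Gaussian /
    empirical table), spatially uniform, scaled so the administered mass
    concentration is met exactly.
    """
    p, init = cfg.particle, cfg.init
    x = _x_grid(cfg)
    dp = _dp_grid(cfg)
    wd = _trapz_weights(dp)
    L = cfg.media.L

    f = np.zeros_like(dp)  # number fraction density over Dp, integrates to 1
    if init.kind == "delta":
        target = init.mean if init.mean is not None else p.Dp1
        j = int(np.argmin(np.abs(dp - target)))
        f[j] = 1.0 / wd[j]
    elif init.kind == "gaussian":
        mean = init.mean if init.mean is not None else p.Dp1
        g = np.exp(-((dp - mean) ** 2) / (2.0 * init.sigma ** 2))
        g[dp < p.Dp1 - 1e-12] = 0.0  # support cannot precede the primary size
        norm = float(np.sum(wd * g))
        if norm <= 0:
            raise ValueError("empty support after truncation")
        f = g / norm
    else:
        for d, frac in init.table:
            if d < p.Dp1 - 1e-9:
                raise ValueError(
                    "initial support cannot extend below the primary diameter"
                )
            j = int(np.argmin(np.abs(dp - d)))
            f[j] += frac / wd[j]
        norm = float(np.sum(wd * f))
        f /= norm

    m = mass_per_particle(dp, p)
    denom = float(np.sum(wd * f * m))  # mean particle mass under f
    n0 = p.C0 * cfg.media.V / denom if p.C0 > 0 else 0.0
    values = n0 * np.broadcast_to(f / L, (x.size, dp.size)).copy()
    return NumberDensityField(values=values, x_nodes=x, dp_nodes=dp, time=0.0)


# ---------------------------------------------------------------------------
# x-transport operator (per size bin, constant in time)
# ---------------------------------------------------------------------------


def _transport_operator(cfg: SystemConfig, x: np.ndarray, D: float, V: float):
    """Semi-discrete finite-volume operator for one size bin.

    Returns (A, n_unknown, slave): A acts on the unknown node values. Under
    the absorptive / Robin bottom conditions the bottom node is slaved to
    its neighbour as N_bottom = slave * N_{n-2} (slave = 0 is absorptive);
    under no-flux every node is an unknown (slave is None). The top face
    always carries zero total flux (nothing enters or leaves at the media
    surface).
    """
    n = x.size
    dx = x[1] - x[0]
    u = _trapz_weights(x)
    vp, vm = max(V, 0.0), min(V, 0.0)
    cD, cU = vp + D / dx, vm - D / dx  # face flux F = cD*N_left + cU*N_right

    if cfg.boundary == "noflux":
        n_unk, slave = n, None
    else:
        n_unk = n - 1
        if cfg.boundary == "absorptive" or cfg.robin_alpha == 0.0:
            slave = 0.0
        else:
            alpha = cfg.robin_alpha  # h/m: N_b = alpha * (V N_b - D dN/dx)
            denom = 1.0 - alpha * V + alpha * D / dx
            if denom <= 0.0:
                raise ValueError(
                    "Robin elimination ill-posed (alpha*V too large): refine "
                    "dx or reduce alpha"
                )
            slave = (alpha * D / dx) / denom

    main = np.zeros(n_unk)
    lower = np.zeros(max(n_unk - 1, 0))
    upper = np.zeros(max(n_unk - 1, 0))

    # faces between consecutive unknowns
    for i in range(n_unk - 1):
        main[i] -= cD / u[i]
        upper[i] -= cU / u[i]
        lower[i] += cD / u[i + 1]
        main[i + 1] += cU / u[i + 1]

    if slave is not None:
        # face between the last unknown and the slaved bottom node:
        # F = cD*N_{n-2} + cU*slave*N_{n-2}
        main[-1] -= (cD + cU * slave) / u[n_unk - 1]
    # no-flux: nothing leaves through the bottom face

    A = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
    return A, n_unk, slave


def _build_steppers(cfg: SystemConfig, x: np.ndarray, coeffs, dt: float):
    """Per-bin theta-scheme operators: (LU(theta=1), LU(theta=1/2),
    explicit CN right-hand operator, n_unknown, slave coefficient)."""
    steppers = []
    for D, V in zip(coeffs.D_diff, coeffs.V_t):
        A, n_unk, slave = _transport_operator(cfg, x, float(D), float(V))
        eye = sp.identity(n_unk, format="csc")
        lu_be = splu((eye - dt * A).tocsc())
        lu_cn = splu((eye - 0.5 * dt * A).tocsc())
        rhs_cn = (eye + 0.5 * dt * A).tocsr()
        steppers.append((lu_be, lu_cn, rhs_cn, n_unk, slave))
    return steppers


def robin_boundary_flux(field: NumberDensityField, alpha: float, coeffs) -> np.ndarray:
    """Bottom-boundary deposition flux per size bin (#/h) under the Robin
    condition N = alpha * J at x = L. alpha = 0 recovers the absorptive
    limit (flux evaluated one-sidedly); alpha -> infinity recovers no-flux.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    x, dp = field.x_nodes, field.dp_nodes
    dx = x[1] - x[0]
    wd = _trapz_weights(dp)
    nb, nb1 = field.values[-1, :], field.values[-2, :]
    J = coeffs.V_t * nb - coeffs.D_diff * (nb - nb1) / dx
    if alpha > 0:
        J = nb / alpha
    return wd * J


# ---------------------------------------------------------------------------
# Size advection (explicit conservative upwind with sub-cycling)
# ---------------------------------------------------------------------------


def _advect_size(values: np.ndarray, s: np.ndarray, wd: np.ndarray, dt: float):
    """Advance N in Dp by dt at node speeds s (nm/h), conservative upwind.

    Faces use the average of adjacent node speeds; no flux leaves the grid
    through either size boundary (the floor holds inert cores; growth past
    the initial maximum is reflected, which only matters for supersaturated
    media).
    """
    smax = float(np.abs(s).max())
    if smax == 0.0 or values.size == 0:
        return values
    n_sub = max(1, int(math.ceil(dt * smax / (_CFL_SAFETY * wd.min()))))
    dts = dt / n_sub
    s_face = 0.5 * (s[:-1] + s[1:])  # face j+1/2 between nodes j, j+1
    sp_ = np.maximum(s_face, 0.0)
    sm_ = np.minimum(s_face, 0.0)
    for _ in range(n_sub):
        flux = sp_ * values[:, :-1] + sm_ * values[:, 1:]  # +Dp direction
        div = np.zeros_like(values)
        div[:, :-1] -= flux
        div[:, 1:] += flux
        values = values + dts * div / wd
    return values


# ---------------------------------------------------------------------------
# Main driver
# ---------------------------------------------------------------------------


def _ion_substep(y: np.ndarray, source: float, shares: np.ndarray,
                 cfg: SystemConfig, dt: float) -> np.ndarray:
    """One RK4 step of the ion kinetics with a frozen particle source.

    source (ug/mL/h) is the dissolved-silver production rate; shares split
    it between the free and bound pools. Cell uptake follows the lumped
    diffusion-limited law on the total dissolved concentration (the form
    the uptake parameters were calibrated under); the media loss is
    apportioned to the two phases by their concentration share, which
    conserves silver exactly.
    """
    d, media, upt = cfg.dissolution, cfg.media, cfg.uptake
    nP0 = d.n * media.P0
    k_up = upt.D12 * upt.SA2 / (media.V * upt.Dis2)

    def rhs(yv):
        cf, cp, ccell = yv
        exch = d.k_f2p * cf * (nP0 - cp) - d.k_p2f * cp * (d.C_sat - cf)
        equil = (ccell * media.V / upt.V_cell) / upt.PC21
        flux = k_up * (cf + cp - equil)
        tot = cf + cp
        share_f = cf / tot if tot > 0 else 0.5
        return np.array(
            [
                shares[0] * source - exch - flux * share_f,
                shares[1] * source + exch - flux * (1.0 - share_f),
                flux,
            ]
        )

    k1 = rhs(y)
    k2 = rhs(y + 0.5 * dt * k1)
    k3 = rhs(y + 0.5 * dt * k2)
    k4 = rhs(y + dt * k3)
    return y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def _channel_shares(state: IonState, cfg: SystemConfig) -> np.ndarray:
    """Fraction of shed particle mass entering the free vs bound pools,
    proportional to the three kinetic driving terms."""
    d, P0 = cfg.dissolution, cfg.media.P0
    kf = d.k_f * (d.C_sat - state.C_f)
    kp = d.k_p * (d.n * P0 - state.C_p) + d.k_p2 * (d.n2(P0) * P0 - state.C_p)
    tot = kf + kp
    if tot == 0.0:
        return np.array([0.5, 0.5])
    return np.array([kf / tot, kp / tot])


def simulate(
    cfg: SystemConfig,
    store_fields: bool = False,
    rannacher_steps: int = 2,
    coeffs_override=None,
) -> SimulationResult:
    """Run the coupled particle/ion simulation from t = 0 to t_max.

    Fully deterministic given the configuration. Ions start at zero for
    particle exposures. Observables are reported at the configured output
    times; the balance ledger is appended at each of them.
    ``coeffs_override`` substitutes the per-bin transport coefficients
    (diagnostic runs, e.g. frozen transport).
    """
    field = init_number_density(cfg)
    x, dp = field.x_nodes, field.dp_nodes
    wd = field.dp_weights
    particle, media = cfg.particle, cfg.media
    m_bin = mass_per_particle(dp, particle)

    coeffs = (
        coeffs_override
        if coeffs_override is not None
        else transport_coefficients(particle, media, dp)
    )
    out_times = cfg.grid.resolved_output_times()

    # master step
    if cfg.grid.dt_policy == "fixed":
        dt = cfg.grid.dt
    else:
        s0 = shrink_rate(dp, IonState(), cfg.dissolution, media.P0, particle)
        smax = float(np.abs(s0).max()) if cfg.dissolution_enabled else 0.0
        dt = _DT_CAP if smax == 0 else min(
            _DT_CAP, _CFL_SAFETY * cfg.grid.dDp / smax
        )

    steppers = _build_steppers(cfg, x, coeffs, dt)
    n_unk = steppers[0][3]

    ion = np.zeros(3)
    cell_counts = np.zeros(dp.size)    # deposited particles per size bin
    cell_pmass = 0.0
    ledger = BalanceLedger()
    snapshots = [] if store_fields else None

    n_t = len(out_times)
    series = {
        k: np.zeros(n_t)
        for k in (
            "media_pmass", "cell_pmass", "media_ion", "cell_ion",
            "cf", "cp", "area", "media_count", "cell_count",
        )
    }
    cell_dist = np.zeros((n_t, dp.size))

    def record(k, t):
        counts = field.bin_counts()
        media_pmass = float(counts @ m_bin)
        media_count = float(counts.sum())
        area = particle_surface_area(field, particle).area_total
        series["media_pmass"][k] = media_pmass
        series["cell_pmass"][k] = cell_pmass
        series["media_ion"][k] = media.V * (ion[0] + ion[1])
        series["cell_ion"][k] = media.V * ion[2]
        series["cf"][k] = ion[0]
        series["cp"][k] = ion[1]
        series["area"][k] = area
        series["media_count"][k] = media_count
        series["cell_count"][k] = float(cell_counts.sum())
        cell_dist[k] = cell_counts
        ledger.record(
            t, media_pmass, cell_pmass, media.V * (ion[0] + ion[1]),
            media.V * ion[2], media_count, float(cell_counts.sum()),
        )
        if store_fields:
            snapshots.append((t, field.values.copy()))

    record(0, out_times[0])
    steps_done = 0
    t = out_times[0]
    for k, t_next in enumerate(out_times[1:], start=1):
        n_steps = max(1, int(math.ceil((t_next - t) / dt - 1e-9)))
        dt_loc = (t_next - t) / n_steps
        if abs(dt_loc - dt) > 1e-12 * max(dt, 1.0):
            local_steppers = _build_steppers(cfg, x, coeffs, dt_loc)
        else:
            local_steppers = steppers
        for _ in range(n_steps):
            # (i) vertical transport, per size bin
            counts_before = field.bin_counts()
            vals = field.values
            for j, (lu_be, lu_cn, rhs_cn, _, slave) in enumerate(local_steppers):
                col = vals[:n_unk, j]
                if steps_done < rannacher_steps:
                    new = lu_be.solve(col)
                else:
                    new = lu_cn.solve(rhs_cn @ col)
                vals[:n_unk, j] = new
                if slave is not None:
                    vals[-1, j] = slave * new[-1]
            # the implicit theta scheme may leave round-off-level negatives
            neg = vals < 0.0
            if np.any(neg):
                deficit = -float(vals[neg].sum())
                scale = float(np.abs(vals).max())
                if scale > 0 and deficit > 1e-8 * scale * vals.size:
                    raise RuntimeError(
                        "transport produced significant negative densities "
                        f"(deficit {deficit:.3e}); reduce the time step"
                    )
                vals[neg] = 0.0
            counts_after = field.bin_counts()
            dep = np.maximum(counts_before - counts_after, 0.0)
            cell_counts += dep
            cell_pmass += float(dep @ m_bin)

            # (ii) size advection from dissolution
            state = IonState(*ion)
            if cfg.dissolution_enabled:
                mass_before = float(field.bin_counts() @ m_bin)
                s = np.asarray(
                    shrink_rate(dp, state, cfg.dissolution, media.P0, particle)
                )
                field.values = _advect_size(field.values, s, wd, dt_loc)
                mass_after = float(field.bin_counts() @ m_bin)
                shed = max(mass_before - mass_after, 0.0)
            else:
                shed = 0.0

            # (iii) ion kinetics with the exact shed mass as source
            source = shed / (media.V * dt_loc)
            shares = _channel_shares(state, cfg)
            ion = _ion_substep(ion, source, shares, cfg, dt_loc)
            steps_done += 1
        t = t_next
        field.time = t
        record(k, t)

    return SimulationResult(
        config=cfg,
        times=np.asarray(out_times),
        media_particle_mass=series["media_pmass"],
        cell_particle_mass=series["cell_pmass"],
        media_ion_total=series["media_ion"],
        cell_ion_mass=series["cell_ion"],
        C_f=series["cf"],
        C_p=series["cp"],
        area_series=series["area"],
        media_count=series["media_count"],
        cell_count=series["cell_count"],
        cell_size_distribution=cell_dist,
        dp_nodes=dp,
        final_field=field,
        ledger=ledger,
        snapshots=snapshots,
    )
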