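"""Derived quantities: concentration profiles, size distributions, dose
fractions.

All mass/volume/surface-area bookkeeping uses the core diameter and the
primary material density; the protein corona and agglomerate voids carry
no silver.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ParticleSpec
from .dissolution import _trapz_weights, area_per_particle, mass_per_particle

__all__ = [
    "mass_concentration_profile",
    "number_concentration_profile",
    "number_fraction_density",
    "cell_deposit_report",
    "ion_fraction_in_cell_silver",
    "observables_frame",
]

_M3_TO_ML = 1e6


def mass_concentration_profile(field, particle: ParticleSpec, A: float) -> np.ndarray:
    """Particle mass concentration C(x, t) in ug/mL along the column.

    C(x) = (1/A) * integral of N * v_p * rho_p over Dp, with the primary
    (silver) density.
    """
    wd = _trapz_weights(field.dp_nodes)
    m = mass_per_particle(field.dp_nodes, particle)
    per_length = field.values @ (wd * m)  # ug per m of column
    return per_length / A / _M3_TO_ML


def number_concentration_profile(field, A: float) -> np.ndarray:
    """Particle number concentration C_N(x, t) in #/mL along the column."""
    wd = _trapz_weights(field.dp_nodes)
    return (field.values @ wd) / A / _M3_TO_ML


def number_fraction_density(field, N0: float) -> np.ndarray:
    """Number fraction density n(Dp; x, t) = N / N(0)."""
    if N0 <= 0:
        raise ValueError("N0 must be positive")
    return field.values / N0


def cell_deposit_report(result) -> pd.DataFrame:
    """Cumulative deposited-particle record per output time.

    Columns: time, per-bin counts folded to total count, silver mass and
    primary-surface area of the particles sitting in the cell layer.
    Particles are binned at their size at the moment of deposition.
    """
    dp = result.dp_nodes
    particle = result.config.particle
    m = mass_per_particle(dp, particle)
    a = area_per_particle(dp, particle)
    dist = result.cell_size_distribution
    rows = []
    for t, counts in zip(result.times, dist):
        rows.append(
            dict(
                t_h=t,
                cell_particle_count=float(counts.sum()),
                cell_particle_ug=float(counts @ m),
                cell_particle_area_nm2=float(counts @ a),
            )
        )
    return pd.DataFrame(rows)


def deposited_size_range(result, threshold: float = 1e-9) -> tuple:
    """(min, max) deposited core diameter carrying more than ``threshold``
    of the total deposited count."""
    counts = result.cell_size_distribution[-1]
    total = counts.sum()
    if total <= 0:
        return (np.nan, np.nan)
    sel = counts > threshold * total
    dps = result.dp_nodes[sel]
    return float(dps.min()), float(dps.max())


def media_size_range(field, threshold: float = 1e-9) -> tuple:
    """(min, max) core diameter carrying more than ``threshold`` of the
    remaining media count."""
    counts = field.bin_counts()
    total = counts.sum()
    if total <= 0:
        return (np.nan, np.nan)
    sel = counts > threshold * total
    dps = field.dp_nodes[sel]
    return float(dps.min()), float(dps.max())


def ion_fraction_in_cell_silver(result, t: float) -> float:
    """Fraction of cell-associated silver that arrived as ions, at time t."""
    k = int(np.argmin(np.abs(result.times - t)))
    if not np.isclose(result.times[k], t, atol=1e-9, rtol=1e-9):
        raise ValueError(f"t={t} is not an output time")
    total = result.cell_ion_mass[k] + result.cell_particle_mass[k]
    if total == 0:
        raise ValueError("no cell-associated silver at the requested time")
    return float(result.cell_ion_mass[k] / total)


def observables_frame(result) -> pd.DataFrame:
    """Tidy time-series table of the headline observables (unit-suffixed)."""
    return pd.DataFrame(
        dict(
            t_h=result.times,
            media_particle_ug=result.media_particle_mass,
            cell_particle_ug=result.cell_particle_mass,
            Cf_ugml=result.C_f,
            Cp_ugml=result.C_p,
            Cdiss_ugml=result.C_diss,
            Ccell_ug=result.cell_ion_mass,
            area_nm2=result.area_series,
            media_particle_count=result.media_count,
            cell_particle_count=result.cell_count,
            deposited_fraction=result.deposited_fraction,
        )
    )
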