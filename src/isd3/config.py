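"""System configuration: domain types, validation, defaults and units.

All quantities are stored internally in one canonical unit system:

===========================  =================
column position ``x``        m
particle core diameter       nm
time                         h
mass                         ug
concentration                ug/mL
particle surface area        nm^2
densities                    g/cm^3 (g/mL for fluids)
dissolution rate constants   mL nm^-2 h^-1  (k_f, k_p, k_p2)
ion exchange rate constants  ug^-1 mL h^-1  (k_f2p, k_p2f)
membrane diffusivity D12     cm^2/h
===========================  =================

Rate constants keep the units in which they were calibrated; everything
else is converted once, at load time, by the small unit layer below.
Config files are YAML; any numeric field may be written either as a bare
number (interpreted in the canonical unit) or as a string ``"<value>
<unit>"`` with one of the accepted units for that field.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

__all__ = [
    "MediaSpec",
    "ParticleSpec",
    "DissolutionParams",
    "UptakeParams",
    "GridSpec",
    "InitialDistribution",
    "SystemConfig",
    "ConfigError",
    "load_config",
    "loads_config",
    "write_config",
    "dumps_config",
    "derived_n2",
]


class ConfigError(ValueError):
    """Raised for missing fields, bad units or unphysical values."""


# ---------------------------------------------------------------------------
# Unit layer
# ---------------------------------------------------------------------------

# factor converts *from* the named unit *to* the canonical unit of the group
_UNIT_TABLES = {
    "length_m": {"m": 1.0, "mm": 1e-3, "cm": 1e-2, "um": 1e-6, "nm": 1e-9},
    "length_nm": {"nm": 1.0, "um": 1e3, "m": 1e9},
    "length_cm": {"cm": 1.0, "m": 1e2, "um": 1e-4, "nm": 1e-7},
    "volume_mL": {"mL": 1.0, "ml": 1.0, "L": 1e3, "l": 1e3, "uL": 1e-3, "m^3": 1e6},
    "area_m2": {"m^2": 1.0, "cm^2": 1e-4, "mm^2": 1e-6},
    "area_cm2": {"cm^2": 1.0, "m^2": 1e4, "mm^2": 1e-2},
    "temperature_K": {"K": 1.0},
    "viscosity": {"N*s/m^2": 1.0, "N s/m^2": 1.0, "Pa*s": 1.0, "Pa s": 1.0, "cP": 1e-3},
    "density_gcm3": {"g/cm^3": 1.0, "g/mL": 1.0, "g/ml": 1.0, "kg/m^3": 1e-3, "ug/nm^3": 1e15},
    "conc_ugmL": {"ug/mL": 1.0, "ug/ml": 1.0, "mg/mL": 1e3, "ng/mL": 1e-3, "g/L": 1e3},
    "time_h": {"h": 1.0, "hr": 1.0, "min": 1.0 / 60.0, "s": 1.0 / 3600.0, "d": 24.0},
    "diffusivity_cm2h": {"cm^2/h": 1.0, "m^2/h": 1e4, "cm^2/s": 3600.0, "m^2/s": 3.6e7},
    "rate_mLnm2h": {"mL/nm^2/h": 1.0, "mL nm^-2 h^-1": 1.0},
    "rate_ugmLh": {"mL/ug/h": 1.0, "ug^-1 mL h^-1": 1.0},
    "site_conc": {"ug/mL/FBS%": 1.0, "ug mL^-1 FBS%^-1": 1.0},
    "dimensionless": {"": 1.0, "1": 1.0, "-": 1.0},
    "percent": {"%": 1.0, "FBS%": 1.0},
}


def _convert(value, group: str, fieldname: str) -> float:
    """Coerce a YAML scalar or '<value> <unit>' string to the canonical unit."""
    if isinstance(value, bool):
        raise ConfigError(f"{fieldname}: expected a number, got a boolean")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.strip().split(None, 1)
        try:
            mag = float(parts[0])
        except (ValueError, IndexError):
            raise ConfigError(f"{fieldname}: cannot parse quantity {value!r}") from None
        unit = parts[1].strip() if len(parts) > 1 else ""
        table = _UNIT_TABLES[group]
        if unit not in table:
            raise ConfigError(
                f"{fieldname}: unit {unit!r} not accepted (one of {sorted(table)})"
            )
        return mag * table[unit]
    if isinstance(value, dict) and "value" in value:
        unit = value.get("unit", "")
        return _convert(f"{value['value']} {unit}".strip(), group, fieldname)
    raise ConfigError(f"{fieldname}: cannot interpret {value!r} as a quantity")


def _require_positive(name: str, value: float) -> None:
    if not (value > 0.0) or not math.isfinite(value):
        raise ConfigError(f"{name} must be strictly positive, got {value!r}")


def _require_nonneg(name: str, value: float) -> None:
    if value < 0.0 or not math.isfinite(value):
        raise ConfigError(f"{name} must be non-negative, got {value!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MediaSpec:
    """Liquid column above the cell layer.

    L: column height (m); V: media volume (mL); T: temperature (K);
    mu: dynamic viscosity (N s/m^2); rho_f: media density (g/mL);
    A: bottom (cell) surface area (m^2); P0: serum protein level (FBS %).
    """

    L: float = 0.00315
    V: float = 3.0
    T: float = 310.0
    mu: float = 7.4e-4
    rho_f: float = 1.0
    A: float = 9.52e-4
    P0: float = 10.0

    def __post_init__(self) -> None:
        for name in ("L", "V", "T", "mu", "rho_f", "A", "P0"):
            _require_positive(f"media.{name}", getattr(self, name))
        # V (mL) vs L*A (m^3 -> mL): geometric consistency, warn only
        v_geom = self.L * self.A * 1e6
        if abs(v_geom - self.V) > 0.05 * self.V:
            warnings.warn(
                f"media volume {self.V} mL differs from L*A = {v_geom:.4g} mL "
                "by more than 5%",
                stacklevel=2,
            )


@dataclass
class ParticleSpec:
    """Particle system: primary (core) geometry plus transported state.

    The transported entity is either the bare primary particle, a
    protein-coated particle (core + corona of thickness dRc) or a fractal
    agglomerate. Mass, volume and surface-area bookkeeping always use the
    core diameter and the primary material density.
    """

    Dp1: float = 20.0          # primary core diameter, nm
    rho_p1: float = 10.0       # primary material density, g/cm^3
    state: str = "protein_coated"
    dRc: float = 12.0          # protein-coat thickness, nm
    rho_pc: float = 1.583      # effective transported density, g/cm^3
    DF: Optional[float] = None  # fractal dimension, agglomerates only
    Dmin: float = 10.0         # dissolution floor diameter, nm
    C0: float = 12.5           # initial mass concentration, ug/mL

    def __post_init__(self) -> None:
        _require_positive("particle.Dp1", self.Dp1)
        _require_positive("particle.rho_p1", self.rho_p1)
        _require_nonneg("particle.C0", self.C0)
        _require_nonneg("particle.Dmin", self.Dmin)
        if self.state not in ("primary", "protein_coated", "agglomerate"):
            raise ConfigError(f"unknown particle state {self.state!r}")
        if self.Dmin > self.Dp1:
            raise ConfigError("particle.Dmin must not exceed the primary diameter")
        if self.state == "primary":
            self.dRc = 0.0
            self.rho_pc = self.rho_p1
        elif self.state == "protein_coated":
            _require_nonneg("particle.dRc", self.dRc)
            _require_positive("particle.rho_pc", self.rho_pc)
            if self.rho_pc > self.rho_p1:
                raise ConfigError(
                    "coated effective density cannot exceed the core density"
                )
        else:  # agglomerate
            if self.DF is None or not (1.0 < self.DF <= 3.0):
                raise ConfigError("agglomerate state requires DF in (1, 3]")
            self.dRc = 0.0

    @property
    def Dpc(self) -> float:
        """Effective (transported) diameter at the primary core size, nm."""
        return self.Dp1 + 2.0 * self.dRc

    def effective_diameter(self, Dp):
        """Transported diameter for core diameter ``Dp`` (nm)."""
        if self.state == "protein_coated":
            return Dp + 2.0 * self.dRc
        return Dp


@dataclass
class DissolutionParams:
    """Surface-area-limited dissolution and protein-binding kinetics.

    Defaults are the calibrated silver/FBS values. ``n2`` is never stored:
    it is derived from the pre-factor ``n2c`` and the serum level at use
    time via :func:`derived_n2`.
    """

    k_f: float = 6.00e-18     # particle -> free ion, mL nm^-2 h^-1
    C_sat: float = 1.0        # saturated free-ion concentration, ug/mL
    k_f2p: float = 0.0114     # free -> protein-bound, ug^-1 mL h^-1
    k_p2f: float = 0.016      # protein-bound -> free, ug^-1 mL h^-1
    k_p: float = 3.00e-17     # slow particle -> protein, mL nm^-2 h^-1
    k_p2: float = 1.00e-15    # fast particle -> protein, mL nm^-2 h^-1
    n: float = 0.4            # binding-site conc per FBS%, ug mL^-1 FBS%^-1
    n2c: float = 1.2534       # pre-factor of the fast-site relation

    def __post_init__(self) -> None:
        for name in ("k_f", "C_sat", "k_f2p", "k_p2f", "k_p", "k_p2", "n", "n2c"):
            _require_nonneg(f"dissolution.{name}", getattr(self, name))

    def n2(self, P0: float) -> float:
        return derived_n2(self.n2c, self.n, P0)


@dataclass
class UptakeParams:
    """Diffusion-limited cellular uptake of dissolved ions."""

    D12: float = 9.02e-9      # membrane diffusion coefficient, cm^2/h
    SA2: float = 9.52         # total cell surface area, cm^2 (defaults to A)
    Dis2: float = 7.8e-7      # membrane thickness, cm
    PC21: float = 25.8        # cell:media partition coefficient
    V_cell: float = 1.936e-3  # total cell volume, mL

    def __post_init__(self) -> None:
        for name in ("D12", "SA2", "Dis2", "PC21", "V_cell"):
            _require_positive(f"uptake.{name}", getattr(self, name))


@dataclass
class GridSpec:
    """Numerical grid and time-stepping policy."""

    dx: float = 3.1532e-6     # spatial spacing, m
    dDp: float = 1.0          # size spacing, nm
    t_max: float = 24.0       # horizon, h
    dt_policy: str = "auto_cfl"
    dt: Optional[float] = None  # step, h (fixed policy)
    output_times: Optional[Sequence[float]] = None  # report times, h

    def __post_init__(self) -> None:
        _require_positive("grid.dx", self.dx)
        _require_positive("grid.dDp", self.dDp)
        _require_positive("grid.t_max", self.t_max)
        if self.dt_policy not in ("auto_cfl", "fixed"):
            raise ConfigError(f"unknown dt policy {self.dt_policy!r}")
        if self.dt_policy == "fixed":
            if self.dt is None:
                raise ConfigError("dt_policy=fixed requires grid.dt")
            _require_positive("grid.dt", self.dt)
        if self.output_times is not None:
            times = [float(t) for t in self.output_times]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ConfigError("grid.output_times must be strictly increasing")
            if times and times[-1] > self.t_max + 1e-12:
                raise ConfigError("grid.output_times exceed t_max")
            self.output_times = times

    def resolved_output_times(self) -> list:
        if self.output_times is not None:
            times = list(self.output_times)
        else:
            n = int(round(self.t_max / 0.5))
            times = [0.5 * k for k in range(1, n + 1)]
            if times[-1] < self.t_max - 1e-12:
                times.append(self.t_max)
        if not times or times[0] > 0.0:
            times = [0.0] + [t for t in times if t > 0.0]
        return times


@dataclass
class InitialDistribution:
    """Initial particle size distribution (spatially uniform).

    delta: monodisperse at ``mean`` (defaults to the primary diameter);
    gaussian: mean/sigma, truncated below the primary diameter and
    renormalized; empirical: (diameter, fraction) table.
    """

    kind: str = "delta"
    mean: Optional[float] = None   # nm
    sigma: Optional[float] = None  # nm
    table: Optional[Sequence] = None
    spatial: str = "uniform"

    def __post_init__(self) -> None:
        if self.kind not in ("delta", "gaussian", "empirical"):
            raise ConfigError(f"unknown initial distribution kind {self.kind!r}")
        if self.kind == "gaussian":
            if self.sigma is None or self.sigma <= 0:
                raise ConfigError("gaussian initial distribution requires sigma > 0")
        if self.kind == "empirical":
            if not self.table:
                raise ConfigError("empirical initial distribution requires a table")
            tab = [(float(d), float(f)) for d, f in self.table]
            if any(f < 0 for _, f in tab) or sum(f for _, f in tab) <= 0:
                raise ConfigError("empirical table fractions must be non-negative "
                                  "with positive sum")
            self.table = tab
        if self.spatial != "uniform":
            raise ConfigError("only spatially uniform initial distributions "
                              "are supported")


@dataclass
class SystemConfig:
    """Complete, validated description of one simulation."""

    media: MediaSpec = field(default_factory=MediaSpec)
    particle: ParticleSpec = field(default_factory=ParticleSpec)
    dissolution: DissolutionParams = field(default_factory=DissolutionParams)
    uptake: UptakeParams = field(default_factory=UptakeParams)
    grid: GridSpec = field(default_factory=GridSpec)
    init: InitialDistribution = field(default_factory=InitialDistribution)
    boundary: str = "absorptive"      # absorptive | noflux | robin
    robin_alpha: float = 0.0          # resistance parameter, h/m (robin only)
    dissolution_enabled: bool = True
    ion_initial_bound_fraction: float = 0.85

    def __post_init__(self) -> None:
        if self.boundary not in ("absorptive", "noflux", "robin"):
            raise ConfigError(f"unknown boundary {self.boundary!r}")
        if self.boundary == "robin":
            _require_nonneg("robin_alpha", self.robin_alpha)
        if not (0.0 <= self.ion_initial_bound_fraction <= 1.0):
            raise ConfigError("ion_initial_bound_fraction must lie in [0, 1]")

    def replace(self, **kwargs) -> "SystemConfig":
        """Return a copy with top-level sections replaced."""
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def derived_n2(n2c: float, n: float, P0: float) -> float:
    """Fast protein-binding-site concentration n2 = n2c * n * P0**(-0.403).

    Units follow ``n`` (ug mL^-1 FBS%^-1). The empirical exponent couples the
    apparent fast-site capacity to the serum level.
    """
    if n2c < 0 or n < 0:
        raise ValueError("n2c and n must be non-negative")
    if P0 <= 0:
        raise ValueError("P0 must be strictly positive (P0**-0.403 undefined at 0)")
    return n2c * n * P0 ** (-0.403)


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------

# (section, key) -> (attr, unit group) ; None group = plain float
_SCHEMA = {
    "media": [
        ("height", "L", "length_m"),
        ("volume", "V", "volume_mL"),
        ("temperature", "T", "temperature_K"),
        ("viscosity", "mu", "viscosity"),
        ("density", "rho_f", "density_gcm3"),
        ("area", "A", "area_m2"),
        ("fbs_percent", "P0", "percent"),
    ],
    "particle": [
        ("primary_diameter", "Dp1", "length_nm"),
        ("primary_density", "rho_p1", "density_gcm3"),
        ("coat_thickness", "dRc", "length_nm"),
        ("effective_density", "rho_pc", "density_gcm3"),
        ("fractal_dimension", "DF", None),
        ("dissolution_floor", "Dmin", "length_nm"),
        ("initial_concentration", "C0", "conc_ugmL"),
    ],
    "dissolution": [
        ("k_f", "k_f", "rate_mLnm2h"),
        ("c_sat", "C_sat", "conc_ugmL"),
        ("k_f2p", "k_f2p", "rate_ugmLh"),
        ("k_p2f", "k_p2f", "rate_ugmLh"),
        ("k_p", "k_p", "rate_mLnm2h"),
        ("k_p2", "k_p2", "rate_mLnm2h"),
        ("n", "n", "site_conc"),
        ("n2c", "n2c", None),
    ],
    "uptake": [
        ("d12", "D12", "diffusivity_cm2h"),
        ("sa2", "SA2", "area_cm2"),
        ("dis2", "Dis2", "length_cm"),
        ("pc21", "PC21", None),
        ("v_cell", "V_cell", "volume_mL"),
    ],
    "grid": [
        ("dx", "dx", "length_m"),
        ("d_dp", "dDp", "length_nm"),
        ("t_max", "t_max", "time_h"),
        ("dt", "dt", "time_h"),
    ],
}

_CANONICAL_UNIT = {
    "length_m": "m", "length_nm": "nm", "length_cm": "cm", "volume_mL": "mL",
    "area_m2": "m^2", "area_cm2": "cm^2", "temperature_K": "K",
    "viscosity": "N*s/m^2", "density_gcm3": "g/cm^3", "conc_ugmL": "ug/mL",
    "time_h": "h", "diffusivity_cm2h": "cm^2/h", "rate_mLnm2h": "mL/nm^2/h",
    "rate_ugmLh": "mL/ug/h", "site_conc": "ug/mL/FBS%", "percent": "%",
}

_REQUIRED = {("particle", "primary_diameter"), ("particle", "initial_concentration")}


def _build_section(cls, section: str, data: dict):
    kwargs = {}
    data = dict(data or {})
    for key, attr, group in _SCHEMA[section]:
        if key in data:
            raw = data.pop(key)
            if raw is None:
                continue
            kwargs[attr] = (
                _convert(raw, group, f"{section}.{key}") if group else float(raw)
            )
        elif (section, key) in _REQUIRED:
            raise ConfigError(f"missing required field {section}.{key}")
    # non-numeric extras handled per section
    if section == "particle" and "state" in data:
        kwargs["state"] = str(data.pop("state"))
    if section == "grid":
        for extra in ("dt_policy", "output_times"):
            if extra in data:
                kwargs[extra] = data.pop(extra)
    if data:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(data)}")
    return cls(**kwargs)


def loads_config(text: str) -> SystemConfig:
    """Parse a YAML document into a validated :class:`SystemConfig`."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    doc = dict(doc)
    sections = {
        "media": (MediaSpec, doc.pop("media", {})),
        "particle": (ParticleSpec, doc.pop("particle", None)),
        "dissolution": (DissolutionParams, doc.pop("dissolution", {})),
        "uptake": (UptakeParams, doc.pop("uptake", {})),
        "grid": (GridSpec, doc.pop("grid", {})),
    }
    if sections["particle"][1] is None:
        raise ConfigError("missing required section 'particle'")
    built = {
        name: _build_section(cls, name, data)
        for name, (cls, data) in sections.items()
    }

    init_data = doc.pop("init", {"kind": "delta"}) or {"kind": "delta"}
    init = InitialDistribution(**init_data)

    boundary = doc.pop("boundary", "absorptive")
    robin_alpha = 0.0
    if isinstance(boundary, dict):
        if "robin" in boundary:
            robin_alpha = float(boundary["robin"])
            boundary = "robin"
        else:
            raise ConfigError(f"cannot interpret boundary {boundary!r}")
    cfg = SystemConfig(
        **built,
        init=init,
        boundary=str(boundary),
        robin_alpha=robin_alpha,
        dissolution_enabled=bool(doc.pop("dissolution_enabled", True)),
        ion_initial_bound_fraction=float(doc.pop("ion_initial_bound_fraction", 0.85)),
    )
    if doc:
        raise ConfigError(f"unknown top-level keys: {sorted(doc)}")
    return cfg


def load_config(path) -> SystemConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return loads_config(fh.read())


def _emit_section(obj, section: str) -> dict:
    out = {}
    for key, attr, group in _SCHEMA[section]:
        val = getattr(obj, attr, None)
        if val is None:
            continue
        if group:
            out[key] = f"{val!r} {_CANONICAL_UNIT[group]}"
        else:
            out[key] = float(val)
    if section == "particle":
        out["state"] = obj.state
    if section == "grid":
        out["dt_policy"] = obj.dt_policy
        if obj.output_times is not None:
            out["output_times"] = list(obj.output_times)
    return out


def dumps_config(cfg: SystemConfig) -> str:
    doc = {
        "media": _emit_section(cfg.media, "media"),
        "particle": _emit_section(cfg.particle, "particle"),
        "dissolution": _emit_section(cfg.dissolution, "dissolution"),
        "uptake": _emit_section(cfg.uptake, "uptake"),
        "grid": _emit_section(cfg.grid, "grid"),
        "init": {
            k: v
            for k, v in dataclasses.asdict(cfg.init).items()
            if v is not None
        },
        "boundary": (
            {"robin": cfg.robin_alpha} if cfg.boundary == "robin" else cfg.boundary
        ),
        "dissolution_enabled": cfg.dissolution_enabled,
        "ion_initial_bound_fraction": cfg.ion_initial_bound_fraction,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def write_config(cfg: SystemConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_config(cfg))
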