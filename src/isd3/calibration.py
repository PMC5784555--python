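"""Parameter estimation and identifiability screening.

Dissolution parameters are fitted to dissolved-silver time courses from
cell-free (vial) experiments across serum levels and doses; the two uptake
parameters are fitted to cell-silver time courses from ion-only exposures.
Fits run in log10 parameter space with bounded nonlinear least squares and
multi-start (rate constants span three orders of magnitude). Local
identifiability is screened with finite-difference sensitivity functions
and Brun-style collinearity indices: a parameter subset with index below
~20 is conventionally considered identifiable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .config import SystemConfig
from .dissolution import dissolve_well_mixed, ion_uptake_only

__all__ = [
    "TimeCourseDataset",
    "FitResult",
    "synthesize_timecourse",
    "fit_dissolution",
    "fit_uptake",
    "sensitivity_functions",
    "collinearity_index",
    "identifiable_subsets",
    "DISSOLUTION_PARAMS",
    "UPTAKE_PARAMS",
    "COLLINEARITY_CAP",
]

DISSOLUTION_PARAMS = ("k_f", "C_sat", "k_f2p", "k_p2f", "k_p", "k_p2", "n", "n2c")
UPTAKE_PARAMS = ("D12", "PC21", "Dis2", "SA2")
COLLINEARITY_CAP = 1e6
IDENTIFIABILITY_THRESHOLD = 20.0


@dataclass
class TimeCourseDataset:
    """One measured (or synthesized) concentration time course.

    ``kind`` is 'particle' for dissolved silver from a particle suspension
    (values in ug/mL) or 'ion' for cell silver following an ion-only dose
    (values in ug).
    """

    times: np.ndarray
    values: np.ndarray
    C0: float            # administered concentration, ug/mL
    Dp1: float           # primary diameter, nm (particle kind)
    P0: float            # FBS %
    kind: str = "particle"
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.values.size:
            raise ValueError("times and values must be 1-D and equally long")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")
        if self.kind not in ("particle", "ion"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")


@dataclass
class FitResult:
    estimates: Dict[str, float]
    rss: float
    sensitivity_norms: Dict[str, float]
    collinearity: float
    n_data: int
    seed: Optional[int] = None
    success: bool = True
    message: str = ""
    starts_tried: int = 1


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------


def _condition_config(base: SystemConfig, ds: TimeCourseDataset) -> SystemConfig:
    media = dataclasses.replace(base.media, P0=ds.P0)
    particle = dataclasses.replace(base.particle, Dp1=ds.Dp1, C0=ds.C0)
    return base.replace(media=media, particle=particle)


def _apply_params(cfg: SystemConfig, names: Sequence[str], values) -> SystemConfig:
    diss = {n: v for n, v in zip(names, values) if n in DISSOLUTION_PARAMS}
    upt = {n: v for n, v in zip(names, values) if n in UPTAKE_PARAMS}
    out = cfg
    if diss:
        out = out.replace(dissolution=dataclasses.replace(out.dissolution, **diss))
    if upt:
        out = out.replace(uptake=dataclasses.replace(out.uptake, **upt))
    return out


def dissolution_model(
    cfg: SystemConfig, ds: TimeCourseDataset, rtol: float = 1e-7
) -> np.ndarray:
    """Predicted total dissolved silver C_diss(t) for one vial condition."""
    run_cfg = _condition_config(cfg, ds)
    times = ds.times if ds.times[0] == 0.0 else np.concatenate([[0.0], ds.times])
    res = dissolve_well_mixed(run_cfg, times=times, rtol=rtol)
    cd = res.C_diss
    return cd[-ds.times.size:]


def uptake_model(cfg: SystemConfig, ds: TimeCourseDataset) -> np.ndarray:
    """Predicted cell silver mass (ug) for one ion-only exposure."""
    times = ds.times if ds.times[0] == 0.0 else np.concatenate([[0.0], ds.times])
    res = ion_uptake_only(cfg, ds.C0, times=times)
    mass = cfg.media.V * res.C_cell
    return mass[-ds.times.size:]


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------


def synthesize_timecourse(
    truth: SystemConfig,
    conditions: Sequence[dict],
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> List[TimeCourseDataset]:
    """Generate time-course datasets from model trajectories.

    Each condition is a mapping with keys C0, Dp1 (particle kind) or C0
    (ion kind), P0 and optional kind. Noise is multiplicative Gaussian:
    value * (1 + sd * eps), clipped at zero; deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    out = []
    for cond in conditions:
        kind = cond.get("kind", "particle")
        ds = TimeCourseDataset(
            times=times,
            values=np.zeros_like(times),
            C0=float(cond["C0"]),
            Dp1=float(cond.get("Dp1", truth.particle.Dp1)),
            P0=float(cond.get("P0", truth.media.P0)),
            kind=kind,
        )
        clean = (
            dissolution_model(truth, ds)
            if kind == "particle"
            else uptake_model(_condition_config(truth, ds), ds)
        )
        noisy = clean * (1.0 + noise_sd * rng.standard_normal(times.size))
        ds.values = np.clip(noisy, 0.0, None)
        out.append(ds)
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _residuals_builder(
    cfg: SystemConfig,
    datasets: Sequence[TimeCourseDataset],
    free: Sequence[str],
    model: Callable,
    rel_floor: float = 1e-3,
):
    def residuals(theta):
        trial = _apply_params(cfg, free, 10.0 ** np.asarray(theta))
        res = []
        for ds in datasets:
            pred = model(trial, ds)
            w = (
                ds.weights
                if ds.weights is not None
                else 1.0 / np.maximum(ds.values, rel_floor)
            )
            res.append((pred - ds.values) * w)
        return np.concatenate(res)

    return residuals


def _multistart_fit(
    cfg, datasets, free, model, bounds_decades, n_starts, seed
) -> FitResult:
    current = {
        **dataclasses.asdict(cfg.dissolution),
        **dataclasses.asdict(cfg.uptake),
    }
    p0 = np.array([current[name] for name in free], dtype=float)
    if np.any(p0 <= 0):
        raise ValueError("free parameters must be positive to fit in log space")
    theta0 = np.log10(p0)
    lo, hi = theta0 - bounds_decades, theta0 + bounds_decades
    residuals = _residuals_builder(cfg, datasets, free, model)

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(lo, hi))

    best = None
    for th in starts:
        try:
            sol = least_squares(
                residuals, th, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception:  # pragma: no cover - optimizer hiccup on one start
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[1]:
            best = (sol, rss)
    if best is None:
        raise RuntimeError("all optimization starts failed")
    sol, rss = best

    estimates = dict(zip(free, 10.0 ** sol.x))
    fitted_cfg = _apply_params(cfg, free, [estimates[n] for n in free])
    S, names = sensitivity_functions(
        lambda c: np.concatenate([model(c, ds) for ds in datasets]),
        fitted_cfg, free,
    )
    norms = {n: float(np.linalg.norm(S[:, i])) for i, n in enumerate(names)}
    coll = collinearity_index(S, list(range(len(names))))
    n_data = int(sum(ds.values.size for ds in datasets))
    return FitResult(
        estimates=estimates, rss=rss, sensitivity_norms=norms,
        collinearity=coll, n_data=n_data, seed=seed,
        success=bool(sol.status > 0), message=str(sol.message),
        starts_tried=len(starts),
    )


def fit_dissolution(
    datasets: Sequence[TimeCourseDataset],
    cfg: SystemConfig,
    free: Sequence[str] = ("C_sat", "k_f2p", "k_p2f", "k_p", "k_p2", "n2c"),
    bounds_decades: float = 2.0,
    n_starts: int = 2,
    seed: int = 0,
) -> FitResult:
    """Fit dissolution parameters to dissolved-silver time courses.

    Requires at least two conditions spanning distinct serum or dose
    levels and more than one time point per condition; the fit minimizes
    relative-error-weighted residuals of C_diss(t) from the well-mixed
    vial model.
    """
    data = [ds for ds in datasets if ds.kind == "particle"]
    if not data or any(ds.times.size < 2 for ds in data):
        raise ValueError("need particle datasets with at least two time points")
    if len({(ds.P0, ds.C0) for ds in data}) < 2:
        raise ValueError("need at least two conditions (distinct P0 or C0)")
    unknown = set(free) - set(DISSOLUTION_PARAMS)
    if unknown:
        raise ValueError(f"unknown dissolution parameters: {sorted(unknown)}")
    return _multistart_fit(
        cfg, data, list(free), dissolution_model, bounds_decades, n_starts, seed
    )


def fit_uptake(
    datasets: Sequence[TimeCourseDataset],
    cfg: SystemConfig,
    free: Sequence[str] = ("D12", "PC21"),
    bounds_decades: float = 2.0,
    n_starts: int = 2,
    seed: int = 0,
) -> FitResult:
    """Fit ion-uptake parameters to cell-silver time courses (ion-only
    exposures, initial protein-bound fraction applied)."""
    data = [ds for ds in datasets if ds.kind == "ion"]
    if not data or any(ds.times.size < 2 for ds in data):
        raise ValueError("need ion datasets with at least two time points")
    unknown = set(free) - set(UPTAKE_PARAMS)
    if unknown:
        raise ValueError(f"unknown uptake parameters: {sorted(unknown)}")

    def model(trial_cfg, ds):
        return uptake_model(_condition_config(trial_cfg, ds), ds)

    return _multistart_fit(cfg, data, list(free), model, bounds_decades, n_starts, seed)


# ---------------------------------------------------------------------------
# Sensitivity and collinearity
# ---------------------------------------------------------------------------


def sensitivity_functions(
    output_fn: Callable[[SystemConfig], np.ndarray],
    cfg: SystemConfig,
    params: Sequence[str],
    perturbation: float = 0.10,
):
    """Finite-difference local sensitivities of a model output.

    Column j holds (y(p_j*(1+d)) - y(p_j*(1-d))) / (2*d), normalized by the
    output scale — the dimensionless response of the trajectory to a
    relative change in parameter j.
    """
    if perturbation <= 0:
        raise ValueError("perturbation must be positive")
    y0 = np.asarray(output_fn(cfg), dtype=float)
    scale = max(float(np.abs(y0).mean()), 1e-30)
    current = {
        **dataclasses.asdict(cfg.dissolution),
        **dataclasses.asdict(cfg.uptake),
    }
    cols = []
    for name in params:
        p = current[name]
        up = _apply_params(cfg, [name], [p * (1.0 + perturbation)])
        dn = _apply_params(cfg, [name], [p * (1.0 - perturbation)])
        dy = (np.asarray(output_fn(up)) - np.asarray(output_fn(dn))) / (
            2.0 * perturbation
        )
        cols.append(dy / scale)
    return np.column_stack(cols), list(params)


def collinearity_index(S: np.ndarray, subset: Sequence[int]) -> float:
    """Brun-style collinearity index of a column subset of a sensitivity
    matrix: 1/sqrt(min eigenvalue of normalized S'S). 1 means orthogonal
    columns; large values mean the subset's effects can compensate each
    other. Capped at COLLINEARITY_CAP."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    S = np.asarray(S, dtype=float)[:, subset]
    norms = np.linalg.norm(S, axis=0)
    if np.any(norms == 0):
        raise ValueError("rank-deficient normalization: zero sensitivity column")
    Sn = S / norms
    eig = np.linalg.eigvalsh(Sn.T @ Sn)
    lam = max(float(eig[0]), 0.0)
    if lam < 1.0 / COLLINEARITY_CAP ** 2:
        return COLLINEARITY_CAP
    return 1.0 / np.sqrt(lam)


def identifiable_subsets(
    S: np.ndarray,
    names: Sequence[str],
    size: int,
    threshold: float = IDENTIFIABILITY_THRESHOLD,
) -> List[tuple]:
    """All parameter subsets of the given size with collinearity index below
    the identifiability threshold, sorted by index."""
    rows = []
    for combo in combinations(range(len(names)), size):
        gamma = collinearity_index(S, combo)
        if gamma < threshold:
            rows.append((gamma, tuple(names[i] for i in combo)))
    rows.sort(key=lambda r: r[0])
    return rows
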