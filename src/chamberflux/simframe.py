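"""Monte-Carlo framework for evaluating flux calculation schemes.

Synthetic closures are generated from the HMR forward model over a grid
of true initial fluxes f0 and curvatures kappa; every scheme is applied
to the *same* simulated series (a paired design), and per-cell summary
maps are derived:

* ``median`` of the flux estimates (the quantity mapped in heatmaps),
* ``iq90``   — 95th minus 5th percentile, the uncertainty metric,
* ``bias``   — mean estimate minus true f0,
* ``variance`` and ``mse = bias^2 + variance``.

Sensitivity sweeps rerun the grid across instrument precisions (sd_gc)
or deployment durations (t_max), and a measured (or fixture) flux
dataset can be projected onto the grid as a 2-D histogram to weight the
cell metrics by how often each (flux, kappa) region actually occurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    ChamberSystem,
    ConcentrationSeries,
    ConfigurationError,
    HmrParameters,
    InvalidInputError,
    conversion_factor,
    effective_height,
    hmr_concentration,
)
from .regression import fit_hmr, fit_linear, fit_robust_linear
from .schemes import FluxDecision, SchemeConfig, decide_from_fits

__all__ = [
    "DEFAULT_TIMES",
    "default_f0_grid",
    "default_kappa_grid",
    "GridSpec",
    "CellMetrics",
    "SimGridResult",
    "ProjectionResult",
    "simulate_series",
    "run_grid",
    "sweep_parameter",
    "project_dataset",
    "hmr_transition_kappa",
]

DEFAULT_TIMES = (0.0, 720.0, 1440.0, 2160.0)  # 0/12/24/36 min in seconds


def default_f0_grid(n: int = 25, f_min: float = 0.01, f_max: float = 5.0) -> np.ndarray:
    """Zero plus ``n - 1`` log-spaced fluxes in [f_min, f_max], nmol s^-1 m^-2."""
    return np.concatenate(
        [[0.0], np.logspace(math.log10(f_min), math.log10(f_max), n - 1)]
    )


def default_kappa_grid(n: int = 25, k_min: float = 1e-6, k_max: float = 1e-2) -> np.ndarray:
    """``n`` log-spaced curvatures in [k_min, k_max], s^-1."""
    return np.logspace(math.log10(k_min), math.log10(k_max), n)


def _default_system() -> ChamberSystem:
    return ChamberSystem(volume=0.014, area=0.07)


@dataclass(frozen=True)
class GridSpec:
    """Specification of one simulation grid run."""

    f0_values: np.ndarray = field(default_factory=default_f0_grid)
    kappa_values: np.ndarray = field(default_factory=default_kappa_grid)
    n_mc: int = 50
    times: Tuple[float, ...] = DEFAULT_TIMES
    system: ChamberSystem = field(default_factory=_default_system)
    seed: int = 0

    def __post_init__(self) -> None:
        f0 = np.asarray(self.f0_values, dtype=float)
        ka = np.asarray(self.kappa_values, dtype=float)
        object.__setattr__(self, "f0_values", f0)
        object.__setattr__(self, "kappa_values", ka)
        if f0.size == 0 or ka.size == 0:
            raise InvalidInputError("grids must be non-empty")
        if np.any(np.diff(f0) <= 0) or np.any(np.diff(ka) <= 0):
            raise InvalidInputError("grids must be strictly increasing")
        if np.any(ka <= 0):
            raise InvalidInputError("all kappa values must be > 0")
        if self.n_mc < 2:
            raise InvalidInputError("n_mc must be >= 2")


@dataclass(frozen=True)
class CellMetrics:
    """Per-(f0, kappa) summary maps for one scheme; arrays shaped (n_f0, n_kappa)."""

    median: np.ndarray
    iq90: np.ndarray
    bias: np.ndarray
    variance: np.ndarray
    mse: np.ndarray
    hmr_fraction: np.ndarray


@dataclass(frozen=True)
class SimGridResult:
    """Result of one grid run: metrics per scheme, raw estimates optional."""

    spec: GridSpec
    metrics: Dict[str, CellMetrics]
    estimates: Optional[Dict[str, np.ndarray]] = None  # (n_f0, n_kappa, n_mc)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per scheme x f0 x kappa cell."""
        rows = []
        for scheme, m in self.metrics.items():
            for i, f0 in enumerate(self.spec.f0_values):
                for j, ka in enumerate(self.spec.kappa_values):
                    rows.append(
                        {
                            "scheme": scheme,
                            "f0_true_nmol_s_m2": f0,
                            "kappa_true_per_s": ka,
                            "median_nmol_s_m2": m.median[i, j],
                            "iq90_nmol_s_m2": m.iq90[i, j],
                            "bias_nmol_s_m2": m.bias[i, j],
                            "variance_nmol2_s2_m4": m.variance[i, j],
                            "mse_nmol2_s2_m4": m.mse[i, j],
                            "hmr_fraction": m.hmr_fraction[i, j],
                        }
                    )
        return pd.DataFrame(rows)


def simulate_series(
    f0: float,
    kappa: float,
    spec: GridSpec,
    rng: Optional[np.random.Generator] = None,
) -> ConcentrationSeries:
    """One synthetic closure from the HMR forward model plus instrument noise.

    The noiseless curve is anchored at ``C(0) = c0_ambient``; ``kappa = 0``
    is handled as the exact linear limit (slope ``f0 / h`` in matched
    units).  i.i.d. Gaussian noise of sd_gc is added to every sample.
    """
    if kappa < 0:
        raise InvalidInputError("kappa must be >= 0")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times, dtype=float)
    system = spec.system
    conv = conversion_factor(system)
    h = effective_height(system)
    if kappa == 0.0:
        clean = system.c0_ambient + (f0 / conv) / h * t
    else:
        phi = system.c0_ambient + f0 / (conv * kappa * h)
        params_ok = f0 != 0.0
        if params_ok:
            clean = hmr_concentration(HmrParameters(phi, f0, kappa), t, system)
        else:
            clean = np.full_like(t, system.c0_ambient)
    noise = rng.normal(0.0, system.sd_gc, size=t.size) if system.sd_gc > 0 else 0.0
    return ConcentrationSeries(times=t, concentrations=clean + noise, system=system)


def _cell_rng(seed: int, i: int, j: int) -> np.random.Generator:
    # counter-based substreams: reproducible independent of iteration order
    return np.random.default_rng(np.random.SeedSequence([seed, i, j]))


def run_grid(
    spec: GridSpec,
    schemes: Sequence[SchemeConfig],
    store_estimates: bool = False,
) -> SimGridResult:
    """Evaluate every scheme on the same simulated series over the grid.

    For each (f0, kappa) cell, ``n_mc`` noisy series are generated once
    and every scheme's decision rule is applied to the same base fits —
    a paired comparison, so between-scheme differences are not diluted
    by simulation noise.  Reproducible under ``spec.seed``.
    """
    for cfg in schemes:
        if cfg.scheme == "KAPPAMAX" and cfg.f_det is None:
            raise ConfigurationError(
                "KAPPAMAX scheme in a grid run needs a precomputed f_det"
            )
    tags = [c.scheme for c in schemes]
    if len(set(tags)) != len(tags):
        raise ConfigurationError("duplicate scheme tags in one grid run")

    nf, nk, nm = spec.f0_values.size, spec.kappa_values.size, spec.n_mc
    t_meas = float(spec.times[-1] - spec.times[0])
    need_hmr = any(c.scheme not in ("LR", "RLM") for c in schemes)
    need_rlm = any(c.scheme == "RLM" for c in schemes)

    est = {c.scheme: np.empty((nf, nk, nm)) for c in schemes}
    chose_hmr = {c.scheme: np.zeros((nf, nk, nm), dtype=bool) for c in schemes}

    for i, f0 in enumerate(spec.f0_values):
        for j, kappa in enumerate(spec.kappa_values):
            rng = _cell_rng(spec.seed, i, j)
            for r in range(nm):
                series = simulate_series(f0, kappa, spec, rng)
                lin = fit_linear(series)
                rob = fit_robust_linear(series) if need_rlm else None
                hmr = fit_hmr(series, lin) if need_hmr else None
                for cfg in schemes:
                    d = decide_from_fits(lin, hmr, cfg, t_meas=t_meas, robust_fit=rob)
                    est[cfg.scheme][i, j, r] = d.flux
                    chose_hmr[cfg.scheme][i, j, r] = d.chosen == "hmr"

    metrics: Dict[str, CellMetrics] = {}
    truth = spec.f0_values[:, None]
    for cfg in schemes:
        e = est[cfg.scheme]
        q05, q50, q95 = np.percentile(e, [5, 50, 95], axis=2)
        mean = e.mean(axis=2)
        bias = mean - truth
        variance = e.var(axis=2)  # population variance: mse identity is exact
        metrics[cfg.scheme] = CellMetrics(
            median=q50,
            iq90=q95 - q05,
            bias=bias,
            variance=variance,
            mse=bias**2 + variance,
            hmr_fraction=chose_hmr[cfg.scheme].mean(axis=2),
        )
    return SimGridResult(
        spec=spec, metrics=metrics, estimates=est if store_estimates else None
    )


def _sweep_seed(seed: int, idx: int) -> int:
    return int(np.random.SeedSequence([seed, 104729, idx]).generate_state(1)[0] % 2**31)


def sweep_parameter(
    base_spec: GridSpec,
    parameter: str,
    values: Sequence[float],
    schemes: Sequence[SchemeConfig],
    f_det_n_sim: int = 1000,
    f_det_quantile: float = 0.975,
) -> List[SimGridResult]:
    """Rerun the grid across instrument precisions or deployment times.

    ``parameter`` is ``"sd_gc"`` (ppb) or ``"t_max"`` (total deployment
    time, s; the four sampling times are rescaled to 0, t/3, 2t/3, t).
    For any ``KAPPAMAX`` scheme, f_det is re-simulated (HMR scheme with
    linear fallback, 0.975 quantile by default) for each swept value,
    since the detection limit depends on both precision and deployment
    time.
    """
    from .detection import simulate_f_det  # deferred: detection imports schemes

    if parameter not in ("sd_gc", "t_max"):
        raise ConfigurationError("parameter must be 'sd_gc' or 't_max'")
    if len(values) == 0:
        raise InvalidInputError("values must be non-empty")

    results: List[SimGridResult] = []
    for idx, v in enumerate(values):
        if parameter == "sd_gc":
            if not (v > 0):
                raise InvalidInputError("sd_gc values must be > 0")
            system = replace(base_spec.system, sd_gc=float(v))
            spec = replace(base_spec, system=system)
        else:
            if not (v > 0):
                raise InvalidInputError("t_max values must be > 0")
            times = tuple(np.linspace(0.0, float(v), 4))
            spec = replace(base_spec, times=times)

        run_schemes: List[SchemeConfig] = []
        for cfg in schemes:
            if cfg.scheme == "KAPPAMAX":
                fdet = simulate_f_det(
                    spec.system,
                    spec.times,
                    SchemeConfig(scheme="HMR"),
                    n_sim=f_det_n_sim,
                    quantile=f_det_quantile,
                    seed=_sweep_seed(base_spec.seed, idx),
                )
                cfg = replace(cfg, f_det=fdet.f_det)
            run_schemes.append(cfg)
        results.append(run_grid(spec, run_schemes))
    return results


@dataclass(frozen=True)
class ProjectionResult:
    """A flux dataset binned onto the simulation grid, with weighted metrics."""

    counts: np.ndarray  # (n_f0, n_kappa)
    mean_iq90: float
    mean_bias: float
    mean_mse: float
    scheme: str


def _bin_edges(values: np.ndarray) -> np.ndarray:
    """Inner bin edges: geometric midpoints on log axes, arithmetic near zero."""
    edges = np.empty(values.size - 1)
    for k in range(values.size - 1):
        a, b = values[k], values[k + 1]
        edges[k] = math.sqrt(a * b) if a > 0 and b > 0 else 0.5 * (a + b)
    return edges


def project_dataset(
    decisions: Sequence[FluxDecision],
    grid: SimGridResult,
    scheme: Optional[str] = None,
) -> ProjectionResult:
    """Histogram a set of flux decisions onto the simulation grid.

    Each decision is binned by its estimated flux and fitted kappa.
    Fluxes beyond the grid maximum land in the largest flux bin;
    closures whose kappa could not be fitted land in the largest-kappa
    row (they were calculated linearly and carry the linear scheme's
    low uncertainty there).  The returned mean IQ90/bias/MSE are the
    grid-cell metrics weighted by the histogram counts.
    """
    if len(decisions) == 0:
        raise InvalidInputError("project_dataset needs a non-empty decision list")
    if scheme is None:
        scheme = decisions[0].scheme
    if scheme not in grid.metrics:
        raise ConfigurationError(f"grid result has no metrics for scheme {scheme!r}")

    f0_vals = grid.spec.f0_values
    ka_vals = grid.spec.kappa_values
    f0_edges = _bin_edges(f0_vals)
    ka_edges = _bin_edges(ka_vals)

    counts = np.zeros((f0_vals.size, ka_vals.size), dtype=int)
    for d in decisions:
        i = int(np.searchsorted(f0_edges, d.flux))
        kappa = d.kappa
        j = ka_vals.size - 1 if kappa is None else int(np.searchsorted(ka_edges, kappa))
        counts[i, j] += 1

    m = grid.metrics[scheme]
    total = counts.sum()
    return ProjectionResult(
        counts=counts,
        mean_iq90=float(np.sum(counts * m.iq90) / total),
        mean_bias=float(np.sum(counts * m.bias) / total),
        mean_mse=float(np.sum(counts * m.mse) / total),
        scheme=scheme,
    )


def hmr_transition_kappa(
    grid: SimGridResult,
    scheme: str = "KAPPAMAX",
    threshold: float = 0.5,
    min_f0: float = 0.0,
) -> float:
    """Curvature level where a scheme stops trusting the nonlinear fit.

    For every true-flux column with f0 > ``min_f0``, the largest kappa
    at which the scheme still selects the HMR estimate in at least
    ``threshold`` of the replicates is located; the geometric mean of
    those per-column levels is returned (NaN when the scheme never
    reaches the threshold).
    """
    m = grid.metrics[scheme]
    ka = grid.spec.kappa_values
    levels = []
    for i, f0 in enumerate(grid.spec.f0_values):
        if f0 <= min_f0:
            continue
        accept = m.hmr_fraction[i] >= threshold
        if accept.any():
            levels.append(ka[np.flatnonzero(accept)[-1]])
    if not levels:
        return float("nan")
    return float(np.exp(np.mean(np.log(levels))))
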