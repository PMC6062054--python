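"""Minimal detectable flux (f_det) of a chamber measurement system.

The detection limit is estimated by Monte Carlo: many zero-flux
closures are simulated (constant ambient concentration plus i.i.d.
Gaussian instrument noise of sd_gc), every closure's flux is estimated
with a chosen scheme, and a high quantile of the resulting estimate
distribution is reported as f_det.  For the ordinary linear scheme the
same quantity has a closed normal-theory form, used as cross-check.

The kappa.max decision rule consumes this f_det; its own detection
limit can still be simulated once an f_det (from a prior HMR-based
simulation) is supplied in the scheme configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import (
    ChamberSystem,
    ConcentrationSeries,
    ConfigurationError,
    DegenerateDesignError,
    InvalidInputError,
    conversion_factor,
    effective_height,
)
from .regression import fit_hmr, fit_linear, fit_robust_linear
from .schemes import SchemeConfig, decide_from_fits

__all__ = ["DetectionLimitResult", "simulate_f_det", "analytic_f_det_linear"]


@dataclass(frozen=True)
class DetectionLimitResult:
    """Outcome of one detection-limit simulation."""

    f_det: float
    quantile: float
    n_sim: int
    sd_gc: float
    scheme: str
    seed: int
    population: str = "all"

    def __post_init__(self) -> None:
        if not (0 < self.quantile < 1):
            raise InvalidInputError("quantile must be in (0, 1)")
        if self.n_sim < 100:
            raise InvalidInputError("n_sim must be >= 100")


def simulate_f_det(
    system: ChamberSystem,
    times: Sequence[float],
    scheme_config: SchemeConfig,
    n_sim: int = 1000,
    quantile: float = 0.975,
    seed: int = 0,
    population: str = "all",
    signed: bool = True,
) -> DetectionLimitResult:
    """Monte-Carlo minimal detectable flux of a chamber system.

    Simulates ``n_sim`` zero-flux closures (constant ``c0_ambient`` plus
    Gaussian noise of ``sd_gc`` at the given times, s), estimates each
    flux with the configured scheme and returns the requested empirical
    quantile (linear interpolation) of the estimates.  Deterministic
    given ``seed``.

    ``population`` selects the estimate population for HMR-based
    schemes: ``"all"`` (default) keeps every closure, using the linear
    fallback where the nonlinear fit does not converge — the scheme as
    applied to data; ``"hmr_converged"`` keeps only closures with a
    converged nonlinear fit.  ``signed=False`` takes the quantile of
    absolute estimates instead of signed ones.
    """
    if not (0 < quantile < 1):
        raise InvalidInputError("quantile must be in (0, 1)")
    if n_sim < 100:
        raise InvalidInputError("n_sim must be >= 100")
    if system.sd_gc <= 0:
        raise InvalidInputError("simulate_f_det needs sd_gc > 0")
    if population not in ("all", "hmr_converged"):
        raise InvalidInputError("population must be 'all' or 'hmr_converged'")
    if scheme_config.scheme == "KAPPAMAX" and scheme_config.f_det is None:
        raise ConfigurationError(
            "KAPPAMAX detection limit is circular without a prior f_det; "
            "supply f_det (e.g. from an HMR-based simulation) in the config"
        )

    t = np.asarray(times, dtype=float)
    if t.size < 4:
        raise InvalidInputError("need at least 4 sample times")
    t_meas = float(t[-1] - t[0])

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, system.sd_gc, size=(n_sim, t.size))

    fluxes = np.empty(n_sim)
    keep = np.ones(n_sim, dtype=bool)
    need_hmr = scheme_config.scheme not in ("LR", "RLM")
    for i in range(n_sim):
        series = ConcentrationSeries(
            times=t, concentrations=system.c0_ambient + noise[i], system=system
        )
        lin = fit_linear(series)
        rob = fit_robust_linear(series) if scheme_config.scheme == "RLM" else None
        hmr = fit_hmr(series, lin) if need_hmr else None
        if population == "hmr_converged":
            if hmr is None or not hmr.converged:
                keep[i] = False
                continue
            fluxes[i] = hmr.flux
        else:
            decision = decide_from_fits(
                lin, hmr, scheme_config, t_meas=t_meas, robust_fit=rob
            )
            fluxes[i] = decision.flux

    sample = fluxes[keep]
    if sample.size < 100:
        raise InvalidInputError(
            "fewer than 100 converged estimates; increase n_sim"
        )
    if not signed:
        sample = np.abs(sample)
    f_det = float(np.quantile(sample, quantile))
    return DetectionLimitResult(
        f_det=f_det,
        quantile=quantile,
        n_sim=int(sample.size),
        sd_gc=system.sd_gc,
        scheme=scheme_config.scheme,
        seed=seed,
        population=population,
    )


def analytic_f_det_linear(
    system: ChamberSystem,
    times: Sequence[float],
    sd_gc: Optional[float] = None,
    quantile: float = 0.975,
) -> float:
    """Closed-form detection limit of the ordinary linear scheme.

    Under i.i.d. Gaussian concentration noise the OLS slope of a
    zero-flux closure is normal with standard deviation
    ``sd_gc / sqrt(sum((t - tbar)^2))``; the flux quantile is therefore

        z(quantile) * sd_gc / sqrt(Stt) * h * conversion(ppb -> nmol m^-3).

    Exact for the LR scheme; serves as oracle for the simulation.
    """
    if not (0 < quantile < 1):
        raise InvalidInputError("quantile must be in (0, 1)")
    t = np.asarray(times, dtype=float)
    if np.unique(t).size < 3:
        raise DegenerateDesignError("need at least 3 distinct times")
    if sd_gc is None:
        sd_gc = system.sd_gc
    stt = float(np.sum((t - t.mean()) ** 2))
    if stt <= 0:
        raise DegenerateDesignError("zero time spread")
    z = float(stats.norm.ppf(quantile))
    h = effective_height(system)
    conv = conversion_factor(system)
    return z * sd_gc / math.sqrt(stt) * h * conv
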