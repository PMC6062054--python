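"""Flux calculation schemes: the linear-vs-nonlinear decision layer.

A flux calculation scheme (FCS) turns one closure's concentration series
into a single flux estimate.  The HMR nonlinear estimate removes the
saturation bias of a straight line but is unstable for weakly curved or
noisy data, so every practical scheme is a rule for when to trust it:

* ``LR`` / ``RLM`` — always the (robust) linear estimate.
* ``HMR`` — the nonlinear estimate whenever the fit converges, linear
  otherwise (the fallback is part of the scheme).
* ``AIC`` — whichever of linear/HMR scores the lower Akaike criterion.
* ``GFACTOR`` — HMR unless it amplifies the linear estimate by more than
  a fixed factor (default 4, compared on absolute values).
* ``KAPPAMAX`` — HMR unless the fitted kappa exceeds the dynamic bound

      kappa_max = |f_lin| / (f_det * t_meas)

  built from the linear flux estimate, the system's minimal detectable
  flux and the deployment duration.  Small fluxes and imprecise systems
  thus tolerate less nonlinearity; the bound has the dimension 1/time.
* ``FIXEDKAPPA`` — HMR unless kappa exceeds a fixed threshold
  (expressed in 1/h, default 20), the static variant of the same idea.

Ties at the kappa.max boundary accept the HMR estimate (the threshold is
an upper bound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ConcentrationSeries,
    ConfigurationError,
    FluxFit,
    InvalidInputError,
)
from .regression import fit_hmr, fit_linear, fit_robust_linear

__all__ = [
    "SCHEMES",
    "SchemeConfig",
    "FluxDecision",
    "BatchSummary",
    "kappa_max",
    "select_flux",
    "decide_from_fits",
    "batch_select",
]

SCHEMES = ("LR", "RLM", "HMR", "AIC", "GFACTOR", "KAPPAMAX", "FIXEDKAPPA")


@dataclass(frozen=True)
class SchemeConfig:
    """Configuration of one flux calculation scheme.

    Parameters
    ----------
    scheme : str
        One of :data:`SCHEMES`.
    g_max : float
        Maximum allowed |nonlinear/linear| flux ratio for ``GFACTOR``.
    f_det : float, optional
        Minimal detectable flux (nmol s^-1 m^-2); required by
        ``KAPPAMAX``.
    kappa_fixed : float
        Fixed kappa threshold for ``FIXEDKAPPA``, in 1/h.
    t_meas : float, optional
        Override of the deployment duration (s) used by ``KAPPAMAX``;
        by default the first-to-last sample time difference of each
        series is used.
    """

    scheme: str
    g_max: float = 4.0
    f_det: Optional[float] = None
    kappa_fixed: float = 20.0
    t_meas: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ConfigurationError(
                f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}"
            )
        if not (self.g_max > 1):
            raise ConfigurationError("g_max must be > 1")
        if self.scheme == "KAPPAMAX":
            if self.f_det is None or not (self.f_det > 0):
                raise ConfigurationError("KAPPAMAX requires f_det > 0")
        if self.scheme == "FIXEDKAPPA" and not (self.kappa_fixed > 0):
            raise ConfigurationError("FIXEDKAPPA requires kappa_fixed > 0")
        if self.t_meas is not None and not (self.t_meas > 0):
            raise ConfigurationError("t_meas override must be > 0")


@dataclass(frozen=True)
class FluxDecision:
    """The scheme-selected flux for one closure, with its audit trail.

    ``chosen`` names the fit actually used ("linear", "robust_linear"
    or "hmr"); ``reason`` is a machine-readable rule code explaining the
    choice (e.g. ``hmr_not_converged``, ``kappa_exceeds_max``,
    ``g_factor_exceeded``).  ``kappa_max_value`` carries the computed
    dynamic threshold when the scheme is ``KAPPAMAX``.
    """

    flux: float
    chosen: str
    reason: str
    scheme: str
    linear_fit: Optional[FluxFit] = None
    hmr_fit: Optional[FluxFit] = None
    robust_fit: Optional[FluxFit] = None
    kappa_max_value: Optional[float] = None
    closure_id: Optional[str] = None

    @property
    def kappa(self) -> Optional[float]:
        """Fitted kappa of the underlying HMR fit, if it converged."""
        if self.hmr_fit is not None and self.hmr_fit.converged:
            return self.hmr_fit.params.kappa
        return None


def kappa_max(f_lin: float, f_det: float, t_meas: float) -> float:
    """Dynamic upper bound on kappa: ``|f_lin| / (f_det * t_meas)``.

    Monotone increasing in |f_lin| and decreasing in f_det and t_meas:
    less nonlinearity is allowed for small fluxes and imprecise
    measurement systems.  The absolute value extends the rule
    symmetrically to uptake (negative) fluxes.
    """
    if not (f_det > 0):
        raise InvalidInputError("f_det must be > 0")
    if not (t_meas > 0):
        raise InvalidInputError("t_meas must be > 0")
    return abs(f_lin) / (f_det * t_meas)


def decide_from_fits(
    linear_fit: FluxFit,
    hmr_fit: Optional[FluxFit],
    config: SchemeConfig,
    t_meas: Optional[float] = None,
    robust_fit: Optional[FluxFit] = None,
    closure_id: Optional[str] = None,
) -> FluxDecision:
    """Apply a scheme's decision rule to precomputed base fits.

    This is the workhorse behind :func:`select_flux`; the simulation
    framework calls it directly so that every scheme judges the same
    fitted models for a paired comparison.
    """
    scheme = config.scheme

    def linear(reason: str, kmax: Optional[float] = None) -> FluxDecision:
        return FluxDecision(
            flux=linear_fit.flux,
            chosen="linear",
            reason=reason,
            scheme=scheme,
            linear_fit=linear_fit,
            hmr_fit=hmr_fit,
            robust_fit=robust_fit,
            kappa_max_value=kmax,
            closure_id=closure_id,
        )

    def hmr(reason: str, kmax: Optional[float] = None) -> FluxDecision:
        return FluxDecision(
            flux=hmr_fit.flux,
            chosen="hmr",
            reason=reason,
            scheme=scheme,
            linear_fit=linear_fit,
            hmr_fit=hmr_fit,
            robust_fit=robust_fit,
            kappa_max_value=kmax,
            closure_id=closure_id,
        )

    if scheme == "LR":
        return linear("linear_scheme")
    if scheme == "RLM":
        if robust_fit is None:
            raise ConfigurationError("RLM scheme needs a robust linear fit")
        return FluxDecision(
            flux=robust_fit.flux,
            chosen="robust_linear",
            reason="robust_linear_scheme",
            scheme=scheme,
            linear_fit=linear_fit,
            hmr_fit=hmr_fit,
            robust_fit=robust_fit,
            closure_id=closure_id,
        )

    # every remaining scheme prefers the nonlinear fit but may reject it
    if hmr_fit is None or not hmr_fit.converged:
        return linear("hmr_not_converged")

    if scheme == "HMR":
        return hmr("hmr_converged")
    if scheme == "AIC":
        if hmr_fit.aic < linear_fit.aic:
            return hmr("aic_prefers_hmr")
        return linear("aic_prefers_linear")
    if scheme == "GFACTOR":
        if abs(hmr_fit.flux) > config.g_max * abs(linear_fit.flux):
            return linear("g_factor_exceeded")
        return hmr("g_factor_ok")
    if scheme == "KAPPAMAX":
        tm = config.t_meas if config.t_meas is not None else t_meas
        if tm is None or not (tm > 0):
            raise ConfigurationError("KAPPAMAX needs a positive t_meas")
        kmax = kappa_max(linear_fit.flux, config.f_det, tm)
        if hmr_fit.params.kappa <= kmax:
            return hmr("kappa_within_max", kmax)
        return linear("kappa_exceeds_max", kmax)
    if scheme == "FIXEDKAPPA":
        thr = config.kappa_fixed / 3600.0  # 1/h -> 1/s
        if hmr_fit.params.kappa < thr:
            return hmr("kappa_below_fixed")
        return linear("kappa_exceeds_fixed")
    raise ConfigurationError(f"unknown scheme {scheme!r}")  # pragma: no cover


def select_flux(series: ConcentrationSeries, config: SchemeConfig) -> FluxDecision:
    """Fit the base models to one closure and apply the scheme's rule."""
    linear_fit = fit_linear(series)
    robust_fit = fit_robust_linear(series) if config.scheme == "RLM" else None
    hmr_fit = None if config.scheme in ("LR", "RLM") else fit_hmr(series, linear_fit)
    return decide_from_fits(
        linear_fit,
        hmr_fit,
        config,
        t_meas=series.t_meas,
        robust_fit=robust_fit,
        closure_id=series.closure_id,
    )


@dataclass(frozen=True)
class BatchSummary:
    """Aggregate of one scheme applied to a batch of closures.

    ``deviation_ratio_vs_lr`` is the scheme's arithmetic-mean flux over
    the linear scheme's mean flux on the same closures.  The geometric
    mean uses a positive-shift convention (shift by |min| + epsilon when
    non-positive fluxes are present, unshifted afterwards) and is
    reported alongside the arithmetic mean.
    """

    n: int
    n_hmr_selected: int
    mean_flux: float
    geometric_mean_flux: float
    deviation_ratio_vs_lr: float
    mean_abs_deviation_vs_lr: float


def _geometric_mean_shifted(fluxes: np.ndarray, epsilon: float = 1e-3) -> float:
    mn = float(np.min(fluxes))
    shift = 0.0 if mn > 0 else -mn + epsilon
    return float(np.exp(np.mean(np.log(fluxes + shift))) - shift)


def batch_select(
    series_list: Sequence[ConcentrationSeries],
    config: SchemeConfig,
    geometric_shift_epsilon: float = 1e-3,
) -> Tuple[List[FluxDecision], BatchSummary]:
    """Apply one scheme to every closure in a batch and summarise.

    Returns the per-closure decisions plus a :class:`BatchSummary` with
    the hmr-selected count, mean and geometric-mean flux and the
    deviation ratio against the plain linear scheme evaluated on the
    same closures.
    """
    if len(series_list) == 0:
        raise InvalidInputError("batch_select needs a non-empty series list")
    decisions = [select_flux(s, config) for s in series_list]
    fluxes = np.array([d.flux for d in decisions])
    lin_fluxes = np.array(
        [
            d.linear_fit.flux if d.linear_fit is not None else fit_linear(s).flux
            for d, s in zip(decisions, series_list)
        ]
    )
    mean_lin = float(np.mean(lin_fluxes))
    mean_flux = float(np.mean(fluxes))
    summary = BatchSummary(
        n=len(decisions),
        n_hmr_selected=sum(d.chosen == "hmr" for d in decisions),
        mean_flux=mean_flux,
        geometric_mean_flux=_geometric_mean_shifted(fluxes, geometric_shift_epsilon),
        deviation_ratio_vs_lr=mean_flux / mean_lin if mean_lin != 0 else math.nan,
        mean_abs_deviation_vs_lr=float(np.mean(np.abs(fluxes - lin_fluxes))),
    )
    return decisions, summary
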