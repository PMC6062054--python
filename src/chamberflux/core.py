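"""Core domain types and the forward Hutchinson–Mosier concentration model.

A static (non-steady-state) chamber is a closed enclosure placed on soil;
the trace-gas concentration rise during closure is used to infer the
soil–atmosphere flux.  Because the rising headspace concentration feeds
back on the soil–air diffusion gradient, the concentration–time curve is
expected to saturate.  The Hutchinson–Mosier regression (HMR) model, in
the Pedersen et al. parameterization, describes one chamber closure as

    C(t) = phi + f0 * exp(-kappa * t) / (-kappa * h)

where ``C(t)`` is the headspace mole fraction (ppb) at time ``t`` (s)
after closure, ``phi`` is the asymptotic source concentration the chamber
converges to, ``f0`` is the initial flux at closure (the flux undisturbed
by the chamber), ``kappa`` > 0 is the nonlinearity shape parameter (1/s)
and ``h`` is the effective chamber height (m).  As ``kappa`` -> 0 the
curve degenerates to a straight line of slope ``f0 / h``.

All computation inside the package uses seconds, ppb and nmol.  Fluxes
are expressed in nmol s^-1 m^-2; the ppb <-> nmol m^-3 conversion uses
the ideal-gas molar volume at a configurable temperature and pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "R_GAS",
    "DEFAULT_TEMPERATURE",
    "DEFAULT_PRESSURE",
    "ChamberFluxError",
    "InvalidInputError",
    "DegenerateDesignError",
    "ConfigurationError",
    "ParseError",
    "ChamberSystem",
    "ConcentrationSeries",
    "HmrParameters",
    "LinearParams",
    "FluxFit",
    "ppb_to_amount_concentration",
    "amount_concentration_to_ppb",
    "conversion_factor",
    "effective_height",
    "hmr_concentration",
]

R_GAS = 8.314462618  # J mol^-1 K^-1
DEFAULT_TEMPERATURE = 293.15  # K
DEFAULT_PRESSURE = 101325.0  # Pa


class ChamberFluxError(Exception):
    """Base class for all errors raised by chamberflux."""


class InvalidInputError(ChamberFluxError, ValueError):
    """A value is outside its physical or mathematical domain."""


class DegenerateDesignError(ChamberFluxError, ValueError):
    """The sampling design cannot identify the requested parameters."""


class ConfigurationError(ChamberFluxError, ValueError):
    """A scheme or run configuration is incomplete or inconsistent."""


class ParseError(ChamberFluxError, ValueError):
    """An input table could not be read."""


def ppb_to_amount_concentration(
    x: Union[float, np.ndarray],
    temperature: float = DEFAULT_TEMPERATURE,
    pressure: float = DEFAULT_PRESSURE,
) -> Union[float, np.ndarray]:
    """Convert a mole fraction in ppb to an amount concentration in nmol m^-3.

    Uses the ideal gas law: ``x * 1e-9 * p / (R * T)`` mol m^-3, i.e.
    ``x * p / (R * T)`` nmol m^-3.  At 293.15 K and 101325 Pa one ppb is
    about 41.57 nmol m^-3.
    """
    if temperature <= 0 or pressure <= 0:
        raise InvalidInputError("temperature and pressure must be positive")
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("concentration must be finite")
    out = arr * pressure / (R_GAS * temperature)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def amount_concentration_to_ppb(
    x: Union[float, np.ndarray],
    temperature: float = DEFAULT_TEMPERATURE,
    pressure: float = DEFAULT_PRESSURE,
) -> Union[float, np.ndarray]:
    """Inverse of :func:`ppb_to_amount_concentration`."""
    if temperature <= 0 or pressure <= 0:
        raise InvalidInputError("temperature and pressure must be positive")
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("concentration must be finite")
    out = arr * (R_GAS * temperature) / pressure
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass(frozen=True)
class ChamberSystem:
    """Geometry, ambient conditions and instrument precision of a chamber setup.

    Parameters
    ----------
    volume : float
        Chamber headspace volume, m^3.
    area : float
        Covered soil area, m^2.
    height : float, optional
        Explicit effective-height override, m.  When ``None`` (default)
        the effective height is ``volume / area``.
    temperature : float
        Air temperature used for the ppb <-> nmol m^-3 conversion, K.
    pressure : float
        Air pressure for the same conversion, Pa.
    sd_gc : float
        Instrument precision: standard deviation of repeated
        ambient-standard measurements, ppb.  Assumed constant over the
        calibrated concentration range.
    c0_ambient : float
        Ambient trace-gas baseline concentration at closure, ppb.
    """

    volume: float
    area: float
    height: Optional[float] = None
    temperature: float = DEFAULT_TEMPERATURE
    pressure: float = DEFAULT_PRESSURE
    sd_gc: float = 3.0
    c0_ambient: float = 325.0

    def __post_init__(self) -> None:
        if not (self.volume > 0):
            raise InvalidInputError("chamber volume must be > 0")
        if not (self.area > 0):
            raise InvalidInputError("chamber area must be > 0")
        if self.height is not None and not (self.height > 0):
            raise InvalidInputError("height override must be > 0")
        if not (self.temperature > 0):
            raise InvalidInputError("temperature must be > 0 K")
        if not (self.pressure > 0):
            raise InvalidInputError("pressure must be > 0 Pa")
        if self.sd_gc < 0:
            raise InvalidInputError("sd_gc must be >= 0")

    @property
    def effective_height(self) -> float:
        return effective_height(self)


def effective_height(system: ChamberSystem) -> float:
    """Effective chamber height h in metres: V/A unless explicitly overridden."""
    if system.height is not None:
        return system.height
    return system.volume / system.area


def conversion_factor(system: ChamberSystem) -> float:
    """Multiplier turning ppb into nmol m^-3 at the system's T and p."""
    return float(ppb_to_amount_concentration(1.0, system.temperature, system.pressure))


@dataclass(frozen=True)
class HmrParameters:
    """Fitted (or prescribed) parameters of the HMR concentration model.

    ``phi`` is in ppb, ``f0`` in nmol s^-1 m^-2 and ``kappa`` in s^-1.
    A valid nonlinear fit requires ``kappa > 0``; ``f0`` may take any
    sign (uptake fluxes are negative).
    """

    phi: float
    f0: float
    kappa: float

    def __post_init__(self) -> None:
        if not (self.kappa > 0):
            raise InvalidInputError("kappa must be > 0 for a valid HMR parameter set")


@dataclass(frozen=True)
class LinearParams:
    """Straight-line concentration model: slope in ppb s^-1, intercept in ppb."""

    slope: float
    intercept: float


@dataclass(frozen=True)
class ConcentrationSeries:
    """One chamber closure: sample times (s) and concentrations (ppb).

    Times are stored as given; model fits use times relative to the
    first sample (the closure defines the time origin).
    """

    times: np.ndarray
    concentrations: np.ndarray
    system: ChamberSystem
    closure_id: Optional[str] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        who = f" in closure {self.closure_id!r}" if self.closure_id else ""
        if t.ndim != 1 or c.ndim != 1:
            raise InvalidInputError(f"times and concentrations must be 1-D{who}")
        if t.shape != c.shape:
            raise InvalidInputError(f"times and concentrations differ in length{who}")
        if t.size < 4:
            raise InvalidInputError(f"a closure needs at least 4 samples{who}")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(c)):
            raise InvalidInputError(f"non-finite sample values{who}")
        if t[0] < 0:
            raise InvalidInputError(f"first sample time must be >= 0{who}")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError(f"sample times must be strictly increasing{who}")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def rel_times(self) -> np.ndarray:
        """Times relative to the first sample, s."""
        return self.times - self.times[0]

    @property
    def t_meas(self) -> float:
        """Deployment duration: last minus first sample time, s."""
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class FluxFit:
    """Result of one base estimator applied to one closure.

    ``flux`` and ``se_flux`` are in nmol s^-1 m^-2, ``sse`` in ppb^2.
    When ``converged`` is False no flux or parameters are reported and
    the caller is expected to fall back to a linear estimate.
    """

    method: str  # "linear" | "robust_linear" | "hmr"
    converged: bool
    flux: Optional[float]
    params: Optional[Union[LinearParams, HmrParameters]]
    sse: float
    aic: Optional[float]
    se_flux: Optional[float]
    n: int
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.method not in ("linear", "robust_linear", "hmr"):
            raise InvalidInputError(f"unknown fit method {self.method!r}")
        if not self.converged and (self.flux is not None or self.params is not None):
            raise InvalidInputError("a non-converged fit must not carry flux or params")


def hmr_concentration(
    params: HmrParameters,
    t: Union[float, np.ndarray],
    system: ChamberSystem,
) -> Union[float, np.ndarray]:
    """Forward HMR model: headspace concentration (ppb) at time ``t`` (s).

    ``params.f0`` is converted from nmol s^-1 m^-2 to ppb m s^-1 with the
    system's ideal-gas conversion before evaluating

        C(t) = phi + f0 * exp(-kappa t) / (-kappa h).

    The curve converges to ``phi`` as t -> inf and its implied
    instantaneous flux at time t is ``f0 * exp(-kappa t)``.
    """
    if not (params.kappa > 0):
        raise InvalidInputError("kappa must be > 0")
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise InvalidInputError("time must be >= 0")
    h = effective_height(system)
    f0_c = params.f0 / conversion_factor(system)  # ppb m s^-1
    out = params.phi + f0_c * np.exp(-params.kappa * tt) / (-params.kappa * h)
    return float(out) if np.isscalar(t) or tt.ndim == 0 else out
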