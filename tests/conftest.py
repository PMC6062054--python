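import numpy as np
import pytest

from chamberflux import (
    ChamberSystem,
    ConcentrationSeries,
    HmrParameters,
    conversion_factor,
    effective_height,
    hmr_concentration,
)

CASE_TIMES = np.array([0.0, 720.0, 1440.0, 2160.0])


@pytest.fixture
def case_system() -> ChamberSystem:
    """The manual-chamber case-study system: V=0.014 m3, A=0.07 m2, sd 3 ppb."""
    return ChamberSystem(volume=0.014, area=0.07, sd_gc=3.0, c0_ambient=325.0)


@pytest.fixture
def times4() -> np.ndarray:
    return CASE_TIMES.copy()


def make_hmr_series(
    system: ChamberSystem,
    f0: float,
    kappa: float,
    sd: float = 0.0,
    rng: np.random.Generator | None = None,
    times: np.ndarray = CASE_TIMES,
) -> ConcentrationSeries:
    """Closure generated from the saturating model, anchored at c0."""
    conv = conversion_factor(system)
    h = effective_height(system)
    if kappa == 0.0:
        clean = system.c0_ambient + (f0 / conv) / h * times
    else:
        phi = system.c0_ambient + f0 / (conv * kappa * h)
        clean = hmr_concentration(HmrParameters(phi, f0, kappa), times, system)
    noise = rng.normal(0.0, sd, times.size) if sd > 0 and rng is not None else 0.0
    return ConcentrationSeries(times=times, concentrations=clean + noise, system=system)
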