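import numpy as np
import pytest

from ribodyn.core_models import NonlinearParams
from ribodyn import signatures as sg


@pytest.fixture(scope="session")
def default_params() -> NonlinearParams:
    return NonlinearParams(k1=2.0, k2=2.0, k3=5.0, k4=1.0)


@pytest.fixture(scope="session")
def efficient_params(default_params) -> NonlinearParams:
    """Slow-recycling variant: beta = 4.8, three-stage relaxation."""
    return default_params.replace(k4=0.1)


@pytest.fixture(scope="session")
def strong_separation_params() -> NonlinearParams:
    return NonlinearParams(k1=1.0, k2=5.0, k3=50.0, k4=0.01)


@pytest.fixture(scope="session")
def nonlinear_scans():
    """All 16 inhibition scans of the canonical settings (computed once)."""
    scans = {}
    for setting, p in sg.NONLINEAR_SETTINGS.items():
        for mech in ("k1", "k2", "k3", "k4"):
            scans[(setting, mech)] = sg.inhibition_scan(
                p, mech, setting=setting
            )
    return scans


def ordered_random_params(rng: np.random.Generator) -> NonlinearParams:
    """One random parameter set satisfying the standing ordering assumptions.

    Pools: abundant 40S, scarce factor, 60S in between; fast elongation;
    recycling the slowest first-order rate.  Rejection sampling against
    ``ordering_satisfied`` keeps the draw honest.
    """
    while True:
        total_40S = 100.0
        total_60S = rng.uniform(12.0, 40.0)
        total_eIF4F = rng.uniform(1.0, min(10.0, total_60S / 2.0))
        k1 = rng.uniform(0.5, 5.0)
        k2 = rng.uniform(0.5, 5.0)
        k4 = min(k2, k1 * total_eIF4F) / rng.uniform(1.5, 50.0)
        k3 = rng.uniform(10.0, 100.0) * max(k2, k4) / total_60S * 10.0
        p = NonlinearParams(
            k1=k1, k2=k2, k3=k3, k4=k4,
            total_40S=total_40S, total_60S=total_60S,
            total_eIF4F=total_eIF4F,
        )
        if p.ordering_satisfied():
            return p
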