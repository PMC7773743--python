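import numpy as np
import pytest

from rwgkinetics import (
    AdhesionKineticParams,
    InitialState,
    KineticTrace,
    SignalCalibration,
    predict_signal,
    simulate,
)

BASELINE = AdhesionKineticParams(k1=0.1 / 600.0, k2=0.1, k3=0.7, I_max=0.3)


@pytest.fixture(scope="session")
def init():
    return InitialState()


@pytest.fixture(scope="session")
def cal():
    return SignalCalibration()


@pytest.fixture(scope="session")
def baseline_params():
    return BASELINE


@pytest.fixture(scope="session")
def time_grid():
    """0-100 min sampled every 0.5 min."""
    return np.arange(0.0, 100.05, 0.5)


@pytest.fixture(scope="session")
def clean_signal(baseline_params, init, cal, time_grid):
    """Noiseless baseline model signal in pm."""
    return predict_signal(simulate(baseline_params, init, time_grid), cal)


@pytest.fixture(scope="session")
def clean_triplicate(time_grid, clean_signal):
    return [
        KineticTrace(t=time_grid, dlambda=clean_signal, replicate_id=f"r{i + 1}")
        for i in range(3)
    ]


@pytest.fixture(scope="session")
def noisy_triplicate(time_grid, clean_signal):
    """Triplicate with additive Gaussian noise, SD = 1% of saturation."""
    rng = np.random.default_rng(7)
    sigma = 0.01 * float(clean_signal.max())
    return [
        KineticTrace(
            t=time_grid,
            dlambda=np.maximum(
                clean_signal + rng.normal(0.0, sigma, len(time_grid)), 0.0
            ),
            replicate_id=f"r{i + 1}",
        )
        for i in range(3)
    ]
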