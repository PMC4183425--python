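import numpy as np
import pytest

from synkesten import DistributionSpec, KestenParams
from synkesten.model import Ensemble
from synkesten.population import limiting_sample


@pytest.fixture(scope="session")
def baseline_params() -> KestenParams:
    """Gaussian eps/eta at the estimated per-30-min baseline values."""
    return KestenParams(
        eps=DistributionSpec.gaussian(0.9923, 0.05),
        eta=DistributionSpec.gaussian(0.0077, 0.03),
        dt_minutes=30.0,
    )


@pytest.fixture(scope="session")
def stationary_init(baseline_params) -> np.ndarray:
    """A 1087-synapse stationary sample of the baseline process (unit mean)."""
    sample = limiting_sample(baseline_params, 1087, 2000, seed=1)
    return sample.values


def deterministic_ensemble(a: float, h: float, init, n_steps: int,
                           dt_minutes: float = 30.0) -> Ensemble:
    """Noise-free recursion x_{t+1} = a*x_t + h from mixed initial sizes."""
    init = np.asarray(init, dtype=float)
    sizes = np.empty((init.size, n_steps + 1))
    sizes[:, 0] = init
    for k in range(1, n_steps + 1):
        sizes[:, k] = a * sizes[:, k - 1] + h
    times = np.arange(n_steps + 1) * dt_minutes / 60.0
    alive = np.ones_like(sizes, dtype=bool)
    elim = np.full(init.size, -1)
    return Ensemble(times, sizes, alive, elim)
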