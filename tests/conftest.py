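import numpy as np
import pytest

from weanling import (
    CalibrationConfig,
    CohortConfig,
    PerturbedParams,
    build_schedule,
    simulate_trajectory,
)

#: Canonical perturbed animal: weaning weight 8.91 kg, growth rate 0.05/d
#: decaying at 0.02/d, perturbation depth 0.08/d, recovery on day 9.
REFERENCE_PARAMS = PerturbedParams(W0=8.91, mu0=0.05, D=0.02, C=0.08, ts=9.0)


@pytest.fixture(scope="session")
def schedule():
    """Default post-weaning weighing grid (weaning at 28 d of age)."""
    return build_schedule(CohortConfig(n_animals=1))


@pytest.fixture(scope="session")
def calib_cfg():
    return CalibrationConfig()


@pytest.fixture()
def noiseless_trajectory(schedule):
    """Exact trajectory of the canonical perturbed animal."""
    return simulate_trajectory(
        REFERENCE_PARAMS, schedule, 0.0, np.random.default_rng(0), "ref"
    )


def random_perturbed_params(rng, horizon=75.0):
    """Documented parameter ranges for property sweeps."""
    return PerturbedParams(
        W0=rng.uniform(6.0, 12.0),
        mu0=rng.uniform(0.01, 0.10),
        D=rng.uniform(0.005, 0.05),
        C=rng.uniform(0.0, 0.12),
        ts=rng.uniform(2.0, 30.0),
    )
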