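import numpy as np
import pytest

from qsdyn import DesignSpec, default_truth, generate_dataset, simulate


@pytest.fixture(scope="session")
def truth():
    """Published best-fit growth and kinetic parameters."""
    return default_truth()


@pytest.fixture(scope="session")
def clean_dataset(truth):
    """Noiseless synthetic dataset at the default sampling design."""
    gp, qp = truth
    return generate_dataset(gp, qp, DesignSpec(cv=0.0, seed=1))


@pytest.fixture(scope="session")
def noisy_dataset(truth):
    """5%-CV synthetic dataset, the default noise level."""
    gp, qp = truth
    return generate_dataset(gp, qp, DesignSpec(cv=0.05, seed=7))


@pytest.fixture(scope="session")
def reference_trajectory(truth):
    """Dense 12 h single-culture simulation at the published parameters."""
    gp, qp = truth
    return simulate(gp, qp, np.linspace(0.0, 12.0, 1201))
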