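import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svmpsp import KernelSpec, generate_constant_isi
from svmpsp.patterns import BACKGROUND, TARGET

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def de_kernel():
    """The benchmark kernel: double exponential e^{-t/1.5} - e^{-t}."""
    return KernelSpec("double_exp", tau=1.5, tau_r=1.0)


def make_task(seed=0, n_neurons=10, n_targets=1, n_backgrounds=5):
    """Constant-ISI classification task on [10, 20] ms."""
    rng = np.random.default_rng(seed)
    pats = [
        generate_constant_isi(n_neurons, 10.0, 20.0, rng, label=TARGET)
        for _ in range(n_targets)
    ]
    pats += [
        generate_constant_isi(n_neurons, 10.0, 20.0, rng, label=BACKGROUND)
        for _ in range(n_backgrounds)
    ]
    return pats


@pytest.fixture
def task_1v5():
    return make_task(seed=1)
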