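import numpy as np
import pytest

from ugca.simulator import benchmark_model, simulate
from ugca.var_core import TimeSeriesPanel


@pytest.fixture(scope="session")
def bench_panel() -> TimeSeriesPanel:
    """One seeded low-noise draw of the 6-node benchmark, length 1000."""
    rng = np.random.default_rng(12345)
    model = benchmark_model((1.5, 2.0), rng)
    return simulate(model, 1000, rng)


@pytest.fixture(scope="session")
def bench_panel_long() -> TimeSeriesPanel:
    """A long draw for consistency / parameter-recovery checks."""
    rng = np.random.default_rng(99)
    model = benchmark_model((1.5, 2.0), rng)
    return simulate(model, 5000, rng)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
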