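import numpy as np
import pytest

import ovospec as o


@pytest.fixture(scope="session")
def default_config():
    return o.GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """28 days x 2 eggs/day, three representative modes (fast)."""
    modes = [o.AcquisitionMode("reflection"), o.AcquisitionMode("scatter", 0),
             o.AcquisitionMode("scatter", 40)]
    cfg = o.GeneratorConfig(seed=11)
    return o.simulate_cohort(28, 2, modes, cfg), modes, cfg


@pytest.fixture(scope="session")
def full_cohort():
    """The study-sized cohort: 28 days x 10 eggs, all nine modes."""
    cfg = o.GeneratorConfig(seed=5)
    return o.simulate_cohort(28, 10, o.all_modes(), cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(42)
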