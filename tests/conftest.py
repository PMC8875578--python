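import numpy as np
import pytest
from hypothesis import settings

from magipt.params import Scenario

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture()
def scenario() -> Scenario:
    """Default (baseline magnetic) scenario with shipped parameters."""
    return Scenario()


@pytest.fixture()
def fast_scenario() -> Scenario:
    """Coarse, short-horizon settings for quick transport tests."""
    return Scenario().replace(
        **{
            "solver.dr_min": 1e-5,
            "solver.dr_max": 4e-4,
            "solver.n_theta": 16,
            "solver.dt": 5.0,
            "solver.t_end": 600.0,
            "solver.checkpoint_every": 100.0,
        }
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
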