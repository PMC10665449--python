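import numpy as np
import pytest

from fadsim.engine import GroupSpec, PopulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_config(seed=0, update_mode="synchronous", groups=None, n_agents=4,
                 n_trials=6, m=3):
    return PopulationConfig(
        n_agents=n_agents,
        n_trials=n_trials,
        m=m,
        groups=groups or (GroupSpec(fraction=1.0, x0=0.7),),
        seed=seed,
        update_mode=update_mode,
    )


def reference_config(x0=0.7, seed=0, n_trials=2000, groups=None, m=12):
    """The homogeneous study condition: 200 agents, memory 12, 2000 trials."""
    return PopulationConfig(
        n_agents=200,
        n_trials=n_trials,
        m=m,
        groups=groups or (GroupSpec(fraction=1.0, x0=x0),),
        seed=seed,
    )
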