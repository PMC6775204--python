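import numpy as np
import pytest

import scintax as sx


@pytest.fixture(scope="session")
def grid():
    return sx.make_grid(101)


@pytest.fixture(scope="session")
def run_cache():
    """Memoized library-scenario runs shared across the session."""
    cache: dict = {}

    def get(name: str, gating=None, control: bool = False, seed: int = 1):
        key = (name, gating, control, seed)
        if key not in cache:
            scenario = sx.make_scenario(name, gating=gating)
            if control:
                scenario = scenario.control()
            cache[key] = sx.run_simulation(scenario, seed=seed)
        return cache[key]

    return get
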