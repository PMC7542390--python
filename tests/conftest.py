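import warnings

import numpy as np
import pytest

import zili


@pytest.fixture(autouse=True)
def _quiet_solver_warnings():
    """Iteration-cap warnings from deliberately hard fits are expected noise."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="group coordinate descent hit the iteration cap"
        )
        yield


@pytest.fixture
def chain_theta():
    """Small 3-taxon, 2-state model with all cyclic couplings populated."""
    return zili.PottsParameters(
        p=3,
        K=2,
        main_effects=[[0.5], [-0.3], [0.2]],
        pairwise={(0, 1): [[0.8]], (1, 2): [[-0.6]], (2, 0): [[0.4]]},
    )


@pytest.fixture
def small_dataset():
    """Clean, fast benchmark dataset: strong signal, light zero inflation."""
    config = zili.SimulationConfig(p=10, n=200, emission_sd=0.5, tau=0.1)
    return zili.simulate_dataset(config, seed=11)
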