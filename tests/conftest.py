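import numpy as np
import pytest
from dataclasses import replace

from amhsurv import TABLE_DESIGNS, SimulationDesign, simulate_dataset
from amhsurv.samplers import MCMCConfig, run_chain


@pytest.fixture(scope="session")
def d1_params():
    return TABLE_DESIGNS["D1"]


@pytest.fixture(scope="session")
def d1_small():
    """Seeded uncensored dataset from design D1, n=25."""
    design = SimulationDesign(params=TABLE_DESIGNS["D1"], n=25, seed=1)
    return simulate_dataset(design)


@pytest.fixture(scope="session")
def d1_censored():
    """Seeded D1 dataset, n=60, with ~20% censoring per margin."""
    design = SimulationDesign(
        params=TABLE_DESIGNS["D1"], n=60, censor_pct=20.0, seed=2
    )
    return simulate_dataset(design)


@pytest.fixture(scope="session")
def cross_sampler_outputs():
    """All three chain flavours fitted to one shared D1 dataset (n=100).

    Session-scoped: the posterior-mean agreement, efficiency-ordering and
    stationarity checks all read from these runs.
    """
    design = SimulationDesign(params=TABLE_DESIGNS["D1"], n=100, seed=31)
    data = simulate_dataset(design)
    cfg = MCMCConfig(L=11_000, B=1_000, J=10)
    outs = {}
    for alg, seed in (("A1", 41), ("A2", 42), ("A3", 43)):
        outs[alg] = run_chain(
            data, config=replace(cfg, alpha_algorithm=alg, seed=seed)
        )
    return data, outs
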