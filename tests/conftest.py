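import numpy as np
import pytest

from spinecalc.config import Epoch, GeneratorConfig, build_config
from spinecalc.pipeline import run_study
from spinecalc.synthgen import assign_population, generate_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20221214)


@pytest.fixture(scope="session")
def small_v1_study():
    """A small V1-baseline study processed end to end (shared, read-only)."""
    cfg = build_config(None, "V1-baseline", {"n_spines": 120, "seed": 77})
    return run_study(cfg)


@pytest.fixture(scope="session")
def dark_only_session():
    """Background-only spines over a dark epoch, with rendered traces."""
    cfg = GeneratorConfig(
        seed=55, n_spines=150, region="V1",
        class_mixture={"visual": 0.0, "auditory": 0.0, "network_only": 0.0,
                       "unclassified": 1.0},
        session_layout=[Epoch("dark", 360.0)], timepoints=[-1.0])
    truth = assign_population(cfg)
    traces, events, sched = generate_session(cfg, truth, -1.0)
    return cfg, truth, traces, events, sched
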