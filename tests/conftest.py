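import numpy as np
import pytest
from hypothesis import settings

from gmmdenoise.simulate import SimConfig, run_replicates, simulate

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_replicates():
    """Twenty seeded replicates of the simulation at study-default parameters.

    Shared across tests: computing them once keeps the suite fast while still
    exercising the full-scale conditions (100 true 160-bp variants, 35 PCR
    cycles, 1.5e6 sequencing reads).
    """
    summary, results = run_replicates(SimConfig(), n_reps=20, seed=0,
                                      keep_results=True)
    return summary, results


@pytest.fixture(scope="session")
def sim_result(study_replicates):
    """One full-scale simulated dataset (first replicate of the shared batch)."""
    return study_replicates[1][0]


@pytest.fixture(scope="session")
def small_sim():
    """A reduced simulation (fast) that still produces PCR artefacts."""
    cfg = SimConfig(n_true=10, seq_len=60, pool_reads=2000, n_cycles=20,
                    n_seq_reads=100_000, seed=42)
    return simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
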