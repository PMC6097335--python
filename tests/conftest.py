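import numpy as np
import pandas as pd
import pytest

import enhscreen as es
from enhscreen.io import default_ap1_pwm


@pytest.fixture(scope="session")
def ap1_pwm():
    return default_ap1_pwm()


@pytest.fixture
def small_config():
    """A small but fully featured simulation (fast enough for unit tests)."""
    return es.SimulationConfig(
        n_enhancers=30, n_induced=8,
        n_decoy_unidirectional=6, n_decoy_convergent=4, n_decoy_divergent_far=4,
        seed=42,
    )


@pytest.fixture
def small_world(small_config):
    genome, truth = es.generate_genome(small_config)
    tus, counts, samples = es.generate_tu_counts(truth, small_config)
    return small_config, genome, truth, tus, counts, samples


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


@pytest.fixture
def expr_samples():
    """2-replicate control/induced sample table."""
    return pd.DataFrame(
        {
            "condition": ["control", "control", "induced", "induced"],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["control_1", "control_2", "induced_1", "induced_2"], name="sample_id"),
    )
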