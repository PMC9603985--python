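import numpy as np
import pytest

from viromix.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale study: 3 habitats x 3 cohorts x 10 subjects."""
    return SimulationConfig(
        n_subjects_per_cohort=10,
        n_seed_genomes=10,
        genome_length_range=(5000, 9000),
        n_non_viral_contigs=6,
        n_bacteria=24,
        n_planted_diff=6,
        n_planted_diff_bacteria=4,
        n_planted_edges=4,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
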