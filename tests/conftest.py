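import numpy as np
import pytest

from irnv.synthetic import PlantedRule, SyntheticConfig, generate_dataset, make_fixture


@pytest.fixture(scope="session")
def small_planted_run():
    """A modest generated dataset with one strongly planted fatal rule."""
    planted = PlantedRule(
        antecedent=(("ACT_TY", 2), ("F_T", 1)),
        fatal_probability=0.6,
        target_prevalence=0.01,
    )
    config = SyntheticConfig(n_records=6000, planted=(planted,), seed=7)
    dataset, truth = generate_dataset(config)
    return config, dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def iig_negative():
    return make_fixture("iig_negative")


@pytest.fixture
def support_toy():
    return make_fixture("support_toy")
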