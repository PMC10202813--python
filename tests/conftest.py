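import pytest

from ramscape.simulate import SimulationConfig, make_signature_catalog, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7, n_cases=3, organs_per_case=3, tumors_per_organ=2,
        tier_mutation_counts={"early": 120, "intermediate": 60, "late": 60},
        sv_tier_counts={"early": 40, "intermediate": 20, "late": 30},
        n_naive=60, n_genes=800,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def catalog():
    return make_signature_catalog(seed=7)


@pytest.fixture(scope="session")
def ortho_catalog():
    return make_signature_catalog(names=["S1", "S2", "S3"], orthogonal=True, seed=7)
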