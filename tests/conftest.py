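import pytest

from lgtscan import (
    ReferenceIndex,
    SimConfig,
    generate_references,
    simulate_sample,
)


@pytest.fixture(scope="session")
def sim_config():
    """Small read-level study: enough pairs for every truth class to
    appear, error-free so detection decisions are unambiguous."""
    return SimConfig(
        seed=11,
        host_length=40_000,
        n_host_genes=10,
        n_bacterial_refs=8,
        bacterial_length=3_000,
        n_pairs_per_sample=1_200,
        lgt_rate=0.02,
        microbiome_rate=0.01,
        duplicate_rate=0.005,
        lowcomplexity_rate=0.005,
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def references(sim_config):
    return generate_references(sim_config)


@pytest.fixture(scope="session")
def host_index(references):
    return ReferenceIndex([references.host])


@pytest.fixture(scope="session")
def bact_index(references):
    return ReferenceIndex(list(references.bacterial))


@pytest.fixture(scope="session")
def sample(sim_config, references):
    """One simulated sample: (read pairs, truth table)."""
    return simulate_sample(sim_config, references, "S1")
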