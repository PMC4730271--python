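import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from nucdisorder.data_io import assemble_datasets
from nucdisorder.synthetic_data import (
    SyntheticSpec,
    generate_network,
    generate_proteome,
)

SMALL_SIZES = {
    "nucleolus": 60,
    "chromatin": 50,
    "nuclear_speckle": 40,
    "pml_body": 20,
    "cajal_body": 16,
    "nuclear_lamina": 16,
    "nuclear_pore": 12,
    "perinucleolar": 8,
}


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_nonnuclear=500, compartment_sizes=dict(SMALL_SIZES))


@pytest.fixture(scope="session")
def small_proteome(small_spec):
    return generate_proteome(small_spec, seed=101)


@pytest.fixture(scope="session")
def small_network(small_proteome, small_spec):
    edges, expected = generate_network(small_proteome, small_spec, seed=102)
    return edges, expected


@pytest.fixture(scope="session")
def small_datasets(small_proteome, small_network):
    edges, _ = small_network
    return assemble_datasets(
        small_proteome.records, small_proteome.compartment_map, edges
    )
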