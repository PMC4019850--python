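import pytest

from phosbridge.examples import curated_mini_bundle
from phosbridge.interactome import assemble_interactome
from phosbridge.silac import call_enrichment
from phosbridge.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def mini_bundle():
    return curated_mini_bundle()


@pytest.fixture(scope="session")
def mini_network(mini_bundle):
    calls = {bait: call_enrichment(groups)
             for bait, groups in mini_bundle.protein_groups.items()}
    return assemble_interactome(calls, mini_bundle.literature), calls


@pytest.fixture(scope="session")
def synthetic():
    """Default-condition synthetic bundle with its ground truth and the
    assembled network (shared across tests; generation is deterministic)."""
    bundle, truth = simulate_bundle(SimulationConfig(seed=11))
    calls = {bait: call_enrichment(groups)
             for bait, groups in bundle.protein_groups.items()}
    net = assemble_interactome(calls, bundle.literature)
    return bundle, truth, net, calls
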