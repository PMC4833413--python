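import pytest

from mendelfilter.cascade import CascadeConfig
from mendelfilter.fixtures import CANDIDATE_GENES, KNOWN_CATALOG, fixture_reference_families
from mendelfilter.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def ref_fx():
    return fixture_reference_families()


@pytest.fixture(scope="session")
def sim_study():
    """Default synthetic study: one two-affected-sib family, planted causal
    homozygous variant, 500 background variants, no phenocopies."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def cascade_cfg():
    return CascadeConfig(candidate_genes=CANDIDATE_GENES, known_catalog=KNOWN_CATALOG)
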