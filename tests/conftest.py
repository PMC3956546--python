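import numpy as np
import pytest

from pmedkit import synthetic


@pytest.fixture(scope="session")
def default_world():
    """One default-size synthetic study, shared across tests (read-only)."""
    return synthetic.generate_world(synthetic.SimulationConfig(seed=12345))


SMALL_KB = synthetic.KbSizes(
    target_rules=40, target_drugs=20, biomarker_rules=10,
    biomarker_sensitive_drugs=6, biomarker_unique_drugs=9,
    response_drugs=12, sensitivity_drugs=5, sensitivity_genes=10,
    drug_pool=60, network_extra_nodes=15)


@pytest.fixture(scope="session")
def small_world():
    """A small, fast world for pipeline-shaped tests."""
    cfg = synthetic.SimulationConfig(
        seed=99, n_probes=600, n_ref_samples=20,
        n_tumors_per_type={"lymphoma": 3, "tcc": 3},
        genes_per_type=20, kb_sizes=SMALL_KB,
    )
    return synthetic.generate_world(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
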