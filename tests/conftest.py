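import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study shared by integration-level tests."""
    from reporternet import synthetic

    return synthetic.generate_bundle(
        7,
        n_genes=400,
        dataset_sizes=[(12, 8), (12, 8), (12, 8)],
        n_validation_case=40,
        n_validation_control=15,
        n_tfs=20,
        n_active_tfs=3,
        n_receptors=15,
        n_active_receptors=2,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
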