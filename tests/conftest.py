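import numpy as np
import pytest

import strsel as ss

SEED = 20_240_917


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def schedule():
    return ss.default_schedule()


@pytest.fixture(scope="session")
def small_pool():
    """A small AFD pool for fast full-pipeline tests."""
    return ss.build_afd_pool(
        ss.AFDPoolConfig(pool_size=120, n_haplotypes=150, seed=SEED)
    )


@pytest.fixture(scope="session")
def aso_model():
    return ss.SelectionModelSpec(kind=ss.ModelKind.ASO, s=0.005, alpha=12)


@pytest.fixture(scope="session")
def di_mutation():
    return ss.MutationSpec.for_motif(2)


def pytest_configure(config):
    # derandomize hypothesis so the suite is reproducible across machines
    from hypothesis import settings

    settings.register_profile("repro", derandomize=True, deadline=None)
    settings.load_profile("repro")
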