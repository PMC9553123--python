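import numpy as np
import pytest

from scpfates import default_lineage, simulate_dataset


@pytest.fixture(scope="session")
def small_spec():
    # compact lineage: same topology and mechanisms as the default, fewer
    # genes so unit tests stay fast
    return default_lineage(n_genes=1500, n_program_per_segment=20, n_module=12)


@pytest.fixture(scope="session")
def small_sim(small_spec):
    return simulate_dataset(small_spec, n_cells=200, depth=5.0e4, seed=7)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    from scpfates.qc import normalize_log_fpm

    container, _ = small_sim
    return normalize_log_fpm(container)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
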