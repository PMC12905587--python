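import matplotlib
import pytest

import ecotme as e

matplotlib.use("Agg")


@pytest.fixture(scope="session")
def default_config():
    return e.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(default_config):
    """Default synthetic cell cohort with 4 planted cellular modules."""
    return e.generate_cell_cohort(default_config)


@pytest.fixture(scope="session")
def gep_cohort():
    """20 samples x 8 programs with 6 planted meta-program archetypes."""
    cfg = e.SyntheticConfig(seed=7, n_samples=20, n_cells_per_sample=(100, 200))
    return e.generate_sample_geps(cfg)


@pytest.fixture(scope="session")
def bulk_cohort():
    """Bulk expression + survival with 5 planted prognostic genes."""
    cfg = e.SyntheticConfig(seed=7, n_genes=300, n_bulk_samples=500)
    return e.generate_bulk_survival(cfg)
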