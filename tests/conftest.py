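import pytest

from ependymics.simulate import (
    SimulationConfig, simulate_accessibility, simulate_annotation,
    simulate_bulk_cohort, simulate_sc_cohort,
)

SMALL = SimulationConfig(
    seed=42, n_groups=4, n_genes=600, n_samples_per_group=8,
    n_planted_markers_per_group=60, marker_log2fc=3.0,
    n_populations=4, n_markers_per_population=15, n_cells_per_sample=300,
    n_peaks=300,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def bulk_cohort():
    return simulate_bulk_cohort(SMALL)


@pytest.fixture(scope="session")
def sc_cohort():
    return simulate_sc_cohort(SMALL)


@pytest.fixture(scope="session")
def accessibility_cohort():
    return simulate_accessibility(SMALL)


@pytest.fixture(scope="session")
def annotation():
    return simulate_annotation(SMALL)
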