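import numpy as np
import pytest

from microstab import CountTable, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by the slower tests."""
    cfg = SimulationConfig(seed=1)
    table, meta, scfa, truth = simulate_cohort(cfg)
    return cfg, table, meta, scfa, truth


@pytest.fixture(scope="session")
def flat_block_cohort():
    """No-collapse cohort with planted correlation blocks (60 samples)."""
    cfg = SimulationConfig(
        n_subjects=12,
        timepoints=("S1", "S2", "S3", "S4", "S5"),
        include_family=False,
        n_taxa=100,
        collapse_severity=0.0,
        dropout_rate=0.0,
        module_rho=0.8,
        seed=3,
    )
    table, meta, scfa, truth = simulate_cohort(cfg)
    return cfg, table, meta, scfa, truth


@pytest.fixture
def small_table():
    return CountTable(
        taxon_ids=["t1", "t2", "t3"],
        sample_ids=["s1", "s2"],
        counts=np.array([[5.0, 1.0], [0.0, 2.0], [3.0, 7.0]]),
    )
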