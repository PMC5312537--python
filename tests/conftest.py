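import numpy as np
import pandas as pd
import pytest

from metlocal.simulate import SimulationConfig, generate_cohort, generate_matched_omics, generate_toy_network


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale synthetic study shared by cross-module tests."""
    return SimulationConfig(
        n_young=12, n_old=12, n_ions=60, n_genes=50, n_metabolites=40,
        n_enzymes=12, n_planted_enzymes=4, seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    cohort = generate_cohort(small_config)
    network, db = generate_toy_network(small_config)
    expr, ion_mz, intens, truth = generate_matched_omics(cohort, network, db, small_config)
    return {
        "config": small_config, "cohort": cohort, "network": network, "db": db,
        "expression": expr, "ion_mz": ion_mz, "intensities": intens, "truth": truth,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def donors_two_groups() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "donor_id": [f"Y{i}" for i in range(1, 6)] + [f"O{i}" for i in range(1, 6)],
            "age": [20, 21, 22, 23, 24, 55, 58, 60, 62, 65],
            "group": ["young"] * 5 + ["old"] * 5,
        }
    )
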