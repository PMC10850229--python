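import numpy as np
import pandas as pd
import pytest

from qnta import Dataset, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def synthetic_dataset(default_config) -> Dataset:
    """One default synthetic panel, shared across tests."""
    return generate_dataset(default_config, seed=42)


@pytest.fixture(scope="session")
def noiseless_dataset() -> Dataset:
    cfg = SyntheticConfig(
        intra_chemical_rf_fold_range=1.0, is_noise_cv=0.0, raw_noise_cv=0.0
    )
    return generate_dataset(cfg, seed=7)


@pytest.fixture()
def toy_chemicals() -> pd.DataFrame:
    rows = [
        # id, rt, group, chain
        ("PFCA-1", 4.8, "carboxylic_acid", 6),
        ("PFCA-2", 5.1, "carboxylic_acid", 7),
        ("PFCA-3", 6.0, "carboxylic_acid", 8),
        ("PFSA-1", 4.9, "sulfonic_acid", 8),
        ("TARGET", 5.0, "carboxylic_acid", 8),
    ]
    return pd.DataFrame(
        {
            "chemical_id": [r[0] for r in rows],
            "name": [r[0] for r in rows],
            "retention_time": [r[1] for r in rows],
            "ionizing_group": [r[2] for r in rows],
            "chain_length": [r[3] for r in rows],
            "internal_standard_id": [None] * len(rows),
        }
    )
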