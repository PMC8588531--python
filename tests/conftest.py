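import numpy as np
import pytest

from m2hsn import default_grid, train_dictionary
from m2hsn.cli_pipeline import ExperimentConfig, build_splits


@pytest.fixture(scope="session")
def grid40():
    return default_grid(40)


@pytest.fixture(scope="session")
def veg_splits():
    """Small vegetation-only splits shared by the slower tests."""
    cfg = ExperimentConfig(
        rows=32,
        cols=32,
        class_weights={"vegetation": 1.0},
        split_sizes={"train": 300, "band_select": 150, "eval": 200},
        master_seed=0,
    )
    return build_splits(cfg)


@pytest.fixture(scope="session")
def veg_dict4(veg_splits):
    return train_dictionary(veg_splits["train"], 4, sparsity_target=4, seed=1)


@pytest.fixture(scope="session")
def mixed_splits():
    """Small mixed-land-use splits (with anomalies) shared by the slower tests."""
    cfg = ExperimentConfig(
        rows=32,
        cols=32,
        anomaly_fraction=0.03,
        split_sizes={"train": 300, "band_select": 150, "eval": 200},
        master_seed=7,
    )
    return build_splits(cfg)
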