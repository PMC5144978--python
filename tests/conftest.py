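import numpy as np
import pandas as pd
import pytest

from crossclust import ExpressionDataset, SyntheticConfig, generate_multistudy


@pytest.fixture(scope="session")
def small_config():
    """A fast two-study design with strong planted structure for unit tests."""
    return SyntheticConfig(
        n_datasets=2,
        samples_per_dataset=60,
        n_genes=400,
        k_true=3,
        signature_size=40,
        effect_size=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_collection(small_config):
    return generate_multistudy(small_config)


@pytest.fixture(scope="session")
def default_collection():
    """One draw at the default multi-study design."""
    return generate_multistudy(SyntheticConfig(seed=1))


@pytest.fixture()
def toy_dataset():
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionDataset("toy", values)
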