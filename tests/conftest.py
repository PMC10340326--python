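import numpy as np
import pytest

import nmrlbp as nl


@pytest.fixture(scope="session")
def default_dataset():
    """The full 70 + 70 synthetic dataset under default settings."""
    return nl.generate_dataset(nl.default_synth_params())


@pytest.fixture(scope="session")
def default_labels(default_dataset):
    return np.array(default_dataset.labels)


@pytest.fixture(scope="session")
def exp3_features(default_dataset):
    """riu2 LBP histograms of the rendered default dataset (computed once)."""
    return nl.build_features(default_dataset, "exp3_lbp")


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for fast unit tests (same structure, smaller n)."""
    from dataclasses import replace

    params = replace(nl.default_synth_params(), n_geo=8, n_non=8, n_points=512)
    return nl.generate_dataset(params)
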