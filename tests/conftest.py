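"""Shared fixtures: desk-scale synthetic bundles and one fitted preset run."""

import numpy as np
import pytest
from dataclasses import replace

from tensorfe import TensorFeatureModel, generate_dataset, paper_mimic
from tensorfe.datasets import SyntheticConfig, null_config


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A fast, small variant keeping the preset's effect/noise structure."""
    return replace(
        paper_mimic(seed=7),
        n_mrna=120,
        k_mirna=40,
        signal_mrna_count=10,
        signal_mirna_count=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def mimic_bundle():
    return generate_dataset(paper_mimic())


@pytest.fixture(scope="session")
def mimic_results(mimic_bundle):
    """One full pipeline fit on the documented preset, reused across tests."""
    return TensorFeatureModel(mimic_bundle).fit()


@pytest.fixture(scope="session")
def null_bundle():
    """No planted effects at the preset's scale (for type-I-error checks)."""
    return generate_dataset(null_config(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
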