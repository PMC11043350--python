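import numpy as np
import pandas as pd
import pytest

from scnapipe import simgen


@pytest.fixture(scope="session")
def small_cfg() -> simgen.SimConfig:
    """A small genome/cohort used across unit tests."""
    return simgen.SimConfig(
        n_chrom=4, bins_per_chrom=50,
        n_regions_rows=2, n_regions_cols=2, n_cells_per_region=15,
        n_clones=3, seed=11,
    )


@pytest.fixture(scope="session")
def small_bins(small_cfg) -> pd.DataFrame:
    return simgen.generate_reference(small_cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_bins):
    return simgen.generate_cohort(small_cfg, small_bins)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
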