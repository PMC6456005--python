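import numpy as np
import pandas as pd
import pytest

from zwstrata.simulate import (SimConfig, sample_sheet, simulate_coverage,
                               simulate_genome, simulate_variants)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A small but complete study: all three scaffold classes, modest genome."""
    return SimConfig(
        seed=7,
        n_autosomal_scaffolds=60,
        n_z_scaffolds=10,
        n_youngz_scaffolds=6,
        n_transcripts=300,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_coverage(small_genome, small_cfg):
    return simulate_coverage(small_genome, small_cfg)


@pytest.fixture(scope="session")
def small_variants(small_genome, small_cfg):
    return simulate_variants(small_genome, small_cfg)


@pytest.fixture(scope="session")
def pool_sheet(small_cfg):
    return sample_sheet(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_coverage_frame(depths_f, depths_m, lengths=None):
    """Hand-built coverage table for unit tests."""
    n = len(depths_f)
    return pd.DataFrame(
        {
            "scaffold_id": [f"s{i}" for i in range(n)],
            "length": lengths if lengths is not None else [10_000] * n,
            "mean_depth_female": depths_f,
            "mean_depth_male": depths_m,
        }
    )
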