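import numpy as np
import pandas as pd
import pytest

from lysorna import (
    SimulationConfig,
    default_design,
    simulate_fraction_counts,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=300, seed=11)


@pytest.fixture(scope="session")
def truth_small(small_config):
    return simulate_transcriptome(small_config)


@pytest.fixture(scope="session")
def design_small(small_config):
    return default_design(
        genotypes=sorted(small_config.torin_effect_by_genotype),
        n_replicates=small_config.n_replicates,
    )


@pytest.fixture(scope="session")
def fraction_tables(truth_small, design_small, small_config):
    return simulate_fraction_counts(truth_small, design_small, small_config)


@pytest.fixture()
def tiny_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "biotype": ["bulk_mRNA", "tRNA", "Y_RNA"],
            "length_nt": [2000, 1000, 500],
            "s1": [100.0, 10.0, 4.0],
            "s2": [50.0, 20.0, 6.0],
        }
    )
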