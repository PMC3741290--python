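import numpy as np
import pandas as pd
import pytest

from methlink import (
    SyntheticConfig,
    generate_annotation,
    generate_expression,
    generate_methylation_arrays,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A small but fully populated synthetic cohort used across test modules."""
    return SyntheticConfig(
        n_chromosomes=2,
        chrom_length=5_000_000,
        n_transcripts=150,
        n_cpg_islands=100,
        n_probes=3_000,
        planted_unmeth_normal_only=120,
        planted_unmeth_asthma_only=120,
        planted_unmeth_both=500,
        planted_dual_count=8,
        planted_de_count=60,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return generate_annotation(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_annotation):
    arrays, truth = generate_methylation_arrays(small_config, small_annotation)
    sets, truth = generate_expression(small_config, small_annotation, truth)
    return arrays, sets, truth


def make_results(rows):
    """Build a probe-results table from (probe_id, contrast, estimate, p_adj) tuples."""
    df = pd.DataFrame(rows, columns=["probe_id", "contrast", "estimate", "p_adj"])
    df["stderr"] = 0.1
    df["residual_df"] = 16
    df["moderated_t"] = df["estimate"] / df["stderr"]
    df["p_raw"] = df["p_adj"]
    return df


@pytest.fixture
def results_builder():
    return make_results
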