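"""Shared fixtures: small synthetic datasets and toy tables.

The expensive calibrated dataset-1 material used by the acceptance
tests lives in test_acceptance.py as session-scoped fixtures so the
whole suite computes each screen or strategy run exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from mbpredict.io_filters import OTUTable, SampleCovariates
from mbpredict.synthetic import SimulationConfig, generate_dataset


@pytest.fixture
def toy_table() -> OTUTable:
    counts = np.array([[1, 2, 0], [3, 4, 5], [0, 0, 7], [2, 1, 0]])
    return OTUTable(
        counts=counts,
        totals=counts.sum(axis=1),
        sample_ids=("s1", "s2", "s3", "s4"),
        taxon_ids=("otuA", "otuB", "otuC"),
    )


@pytest.fixture
def toy_covs() -> SampleCovariates:
    return SampleCovariates(
        phenotype=np.array([0, 1, 0, 1]),
        fixed={"age": np.array([30.0, 40.0, 50.0, 60.0]),
               "site": np.array(["x", "y", "x", "y"], dtype=object)},
        random={"grp": np.array(["g1", "g1", "g2", "g2"], dtype=object)},
        sample_ids=("s1", "s2", "s3", "s4"),
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A miniature design used where only structure matters, not scale."""
    return SimulationConfig(
        dataset_id=1, n=60, m=40, n_signal=6,
        total_reads_range=(2_000, 5_000), master_seed=11,
        signal_multiplier=6.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config, replicate=0)
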