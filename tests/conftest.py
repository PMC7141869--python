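"""Shared fixtures: small handmade datasets and a default simulated cohort."""

import numpy as np
import pandas as pd
import pytest

from promiss import QuantMatrix, SampleMetadata, SimulationConfig, simulate


@pytest.fixture
def toy_matrix() -> QuantMatrix:
    """3 proteins x 4 samples with a known missing pattern.

    P1: missing in s1, s2 (baseline) -> alpha(baseline)=1.0, alpha(3m)=0
    P2: missing in s3 only
    P3: complete
    """
    values = pd.DataFrame(
        {
            "s1": [np.nan, 5.0, 1.0],
            "s2": [np.nan, 2.0, 2.0],
            "s3": [3.0, np.nan, 3.0],
            "s4": [4.0, 6.0, 4.0],
        },
        index=["P1", "P2", "P3"],
    )
    return QuantMatrix(values)


@pytest.fixture
def toy_meta() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "participant_id": ["a", "b", "a", "b"],
                "timepoint": ["baseline", "baseline", "3m", "3m"],
                "group": ["HD", "LD", "HD", "LD"],
                "batch": [1, 1, 2, 2],
            },
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests (seed 0)."""
    return simulate(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """A scaled-down cohort for tests that iterate over many seeds."""
    return SimulationConfig(
        n_proteins=160,
        n_detectable=130,
        n_informative=6,
        seed=0,
    )
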