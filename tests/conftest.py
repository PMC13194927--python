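import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ratioscreen.core_io import AbundanceMatrix, SampleInfo
from ratioscreen.synthetic import SimConfig, generate_dataset


@pytest.fixture
def small_cohort():
    """Complete (uncensored) 14-sample cohort with mild/moderate/severe groups."""
    config = SimConfig(
        group_sizes={"mild": 3, "moderate": 7, "severe": 4},
        n_pots=4,
        n_proteins=40,
        censor_quantile=0.0,
        seed=101,
    )
    return generate_dataset(config)


@pytest.fixture
def study_cohort():
    """Study-shaped cohort: 31 samples (3/21/7), 9 POTS, left-censored."""
    config = SimConfig(n_proteins=250, censor_quantile=0.1, seed=202)
    return generate_dataset(config)


@pytest.fixture
def toy_matrix():
    data = pd.DataFrame(
        {
            "S1": [10.0, 12.0, 8.0],
            "S2": [11.0, np.nan, 8.5],
            "S3": [10.5, 12.5, 9.0],
            "S4": [9.5, 13.0, np.nan],
        },
        index=pd.Index(["PA", "PB", "PC"], name="protein_id"),
    )
    return AbundanceMatrix(data)


@pytest.fixture
def toy_info():
    return SampleInfo(
        pd.DataFrame(
            {
                "severity": ["mild", "moderate", "moderate", "severe"],
                "pots": [False, True, False, True],
            },
            index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
        )
    )
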