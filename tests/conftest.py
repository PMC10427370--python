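import numpy as np
import pandas as pd
import pytest

from hmcresponse.io import CountMatrix, SampleSheet
from hmcresponse.synthetic import (SimulationConfig, generate_bulk_cohort,
                                   generate_hmc_cohort,
                                   generate_reference_profiles,
                                   gene_lengths_kb)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_patients=12, n_genes=800, seed=42)


@pytest.fixture(scope="session")
def reference(small_config):
    ref, truth = generate_reference_profiles(small_config)
    return ref, truth


@pytest.fixture(scope="session")
def bulk_cohort(small_config, reference):
    ref, _ = reference
    return generate_bulk_cohort(small_config, ref)


@pytest.fixture(scope="session")
def hmc_cohort(small_config):
    return generate_hmc_cohort(small_config)


@pytest.fixture(scope="session")
def lengths(small_config):
    return gene_lengths_kb(small_config)


@pytest.fixture
def toy_counts():
    return CountMatrix(pd.DataFrame(
        {"s1": [10, 20, 30], "s2": [20, 40, 60]},
        index=["a", "b", "c"]))


@pytest.fixture
def trial_sheet():
    """A sheet matching the trial's printed response-category counts:
    19 CR, 9 CRi, 18 TF over 46 patients."""
    responses = ["CR"] * 19 + ["CRi"] * 9 + ["TF"] * 18
    rows = []
    for i, resp in enumerate(responses):
        rows.append(dict(sample_id=f"S{i:02d}", patient_id=f"P{i:02d}",
                         tissue="BM", day=0, dose_mg_m2=50.0, response=resp,
                         os_time=100.0 + i, os_event=0, age=50.0, sex="M"))
    return SampleSheet(pd.DataFrame(rows))
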