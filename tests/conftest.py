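import numpy as np
import pytest
from dataclasses import replace

from vancopk import PopulationModel, default_table1_spec, generate_cohort


TABLE2_THETA = {
    "cl_max": 5.58, "cg50": 93.8, "s": 1.5,
    "vc": 8.02, "vc_icu_cat": 35.7 / 8.02,
    "q": 2.66, "vp": 36.8,
}


@pytest.fixture(scope="session")
def model():
    """Published population estimates (fixed effects, IIV, residual)."""
    return PopulationModel()


@pytest.fixture(scope="session")
def small_cohort(model):
    """40 subjects with the study sampling design, simulated from the
    published model; shared by estimation/diagnostics tests."""
    spec = replace(default_table1_spec(seed=2024), n_subjects=40)
    return generate_cohort(spec, model)


@pytest.fixture(scope="session")
def dense_cohort(model):
    """10 subjects sampled 4-6 times each: informative per-subject data for
    likelihood-approximation checks."""
    spec = replace(
        default_table1_spec(seed=3),
        n_subjects=10,
        samples_per_subject_distribution={"4+": 1.0},
    )
    return generate_cohort(spec, model)


@pytest.fixture(scope="session")
def full_cohort(model):
    """One study-sized cohort (209 subjects) from the published model."""
    return generate_cohort(default_table1_spec(seed=5), model)
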