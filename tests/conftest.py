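import numpy as np
import pytest

from pippk import (
    CohortDesign,
    NPAGConfig,
    final_error_model,
    generate_cohort,
    npag_fit,
)


@pytest.fixture(scope="session")
def error_model():
    return final_error_model()


@pytest.fixture(scope="session")
def fitted(error_model):
    """A population fit on a richly sampled synthetic cohort, reused by the
    posterior/diagnostic/validation tests (slow to build, so session-scoped)."""
    subjects, truth = generate_cohort(CohortDesign.rich(30), seed=3)
    fit = npag_fit(subjects, error_model=error_model, config=NPAGConfig(seed=3))
    return subjects, truth, fit


@pytest.fixture(scope="session")
def sparse_cohort():
    """The default study-like sparse-sampling cohort (24 subjects)."""
    return generate_cohort(CohortDesign(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
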