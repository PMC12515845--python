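import numpy as np
import pytest

from neurotriage import PipelineConfig, run_pipeline
from neurotriage.pipeline import CohortConfig
from neurotriage.synthetic import generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight 8-s subjects — enough structure for unit tests, cheap."""
    return generate_cohort(4, 4, duration_s=8.0, fs=250.0, seed=3)


@pytest.fixture(scope="session")
def full_pipeline_result():
    """One full default run (29 HC + 26 MDD, 90 s, 250 Hz) shared by the
    end-to-end checks; the heavy item of the suite (a few minutes)."""
    return run_pipeline(PipelineConfig(cohort=CohortConfig(seed=0)))
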