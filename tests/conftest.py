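import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from accdist.pipeline import PipelineConfig, run_measure
from accdist.synthvoice import make_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

COHORT_SEED = 1


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default synthetic cohort (20 targets, 10 references), generated once."""
    root = tmp_path_factory.mktemp("cohort")
    return make_cohort(root, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_config(cohort):
    return PipelineConfig(expected_words=cohort.word_labels)


@pytest.fixture(scope="session")
def cohort_full_table(cohort, cohort_config):
    """Full-measure distance table on the default cohort."""
    return run_measure(cohort.targets_dir, cohort.references_dir, cohort_config)


@pytest.fixture(scope="session")
def cohort_truth(cohort):
    """Planted magnitudes and ratings joined on speaker id."""
    mags = pd.read_csv(cohort.magnitudes_csv)
    rats = pd.read_csv(cohort.ratings_csv)
    return mags.merge(rats, on="speaker_id")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
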