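import numpy as np
import pytest

from falldet.preprocessing import PreprocessConfig, preprocess_trials
from falldet.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete multi-subject cohort (3 subjects, 18 trials)."""
    cfg = SyntheticConfig.easy(
        n_young=2, n_elderly=1, trials_per_subject=6,
        adl_duration_s=4.0, rng_seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_blocks(small_cohort):
    """The small cohort preprocessed into a block dataset."""
    return preprocess_trials(small_cohort.trials, PreprocessConfig())
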