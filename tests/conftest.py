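import numpy as np
import pytest

from eegmarkers import CohortConfig, generate_subject_trials, make_subject_specs
from eegmarkers.datasets import TrialSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_trials(rng):
    """White-noise epochs: 20 trials × 4 channels × 1500 samples at 1 kHz."""
    return TrialSet(rng.standard_normal((20, 4, 1500)), 1000.0,
                    [f"ch{i}" for i in range(4)], subject="S0", group="young",
                    condition="c0")


@pytest.fixture(scope="session")
def small_cohort_cfg():
    return CohortConfig(
        n_young=3, n_elderly=3, n_channels=8, n_trials_per_condition=6,
        conditions=("a", "b"), seed=77,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_cfg):
    from eegmarkers import generate_cohort

    return generate_cohort(small_cohort_cfg)


@pytest.fixture(scope="session")
def one_subject_trials():
    """30 trials of one synthetic subject, 8 channels, for detector tests."""
    cfg = CohortConfig(n_young=1, n_elderly=1, n_channels=8,
                       n_trials_per_condition=30, conditions=("c",), seed=5)
    spec = make_subject_specs(cfg)[0]
    return generate_subject_trials(spec, cfg, "c")
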