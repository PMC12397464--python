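import numpy as np
import pytest

from connmed import GroundTruth, RunConfig, run_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort_result():
    """One small synthetic study run shared by pipeline-level tests."""
    cfg = RunConfig(
        synthetic=True,
        n_subjects=24,
        n_rois=10,
        n_volumes=120,
        n_boot=300,
        seed=11,
    )
    return cfg, run_study(cfg)


@pytest.fixture(scope="session")
def default_truth():
    return GroundTruth(seed=0)
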