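import numpy as np
import pytest

from mcipredict.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small separable multimodal cohort with a planted GM effect."""
    cfg = CohortConfig(
        n_per_class=12,
        grid_shape=(8, 9, 8),
        timepoints=("m24", "t0"),
        effect_delta_by_timepoint={"m24": 1.5, "t0": 2.5},
        base_smooth_fwhm_mm=2.0,
        n_scores=10,
        n_informative_scores=3,
        score_effect_d=1.5,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_null_cohort():
    """Same shape as tiny_cohort but with no planted effects anywhere."""
    cfg = CohortConfig(
        n_per_class=12,
        grid_shape=(8, 9, 8),
        timepoints=("m24", "t0"),
        effect_delta_by_timepoint={"m24": 0.0, "t0": 0.0},
        base_smooth_fwhm_mm=2.0,
        n_scores=10,
        n_informative_scores=0,
        score_effect_d=0.0,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
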