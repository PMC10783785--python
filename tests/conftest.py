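import warnings

import pytest

import wsisurv as w

# lifelines/sksurv emit benign fit warnings on small resampled datasets
warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")


@pytest.fixture(scope="session")
def easy_slide():
    """Non-overlapping, high-contrast nuclei: the easy segmentation regime."""
    return w.generate_slide(
        w.SlideSimParams(image_size=512, n_nuclei=40, heterogeneity=0.3, seed=5)
    )


@pytest.fixture(scope="session")
def small_feature_config():
    """Extraction geometry scaled down for synthetic tiles."""
    return w.FeatureConfig(sample_block_size=256, n_blocks=8)


@pytest.fixture(scope="session")
def cohort231():
    """Default-condition simulated cohort (231 patients, informative)."""
    return w.generate_cohort(w.CohortSimParams(seed=1))


#: fast Lasso grid for repeated-split tests (problem-size choice, not tuning)
FAST_LASSO = dict(n_alphas=30, alpha_min_ratio=0.01)
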