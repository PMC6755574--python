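import numpy as np
import pytest

from qsarlab import FixtureSpec, build_plan, make_binary_dataset, run_repeated_cv


@pytest.fixture(scope="session")
def small_dataset():
    """60 compounds, 12 actives, narrow descriptor sets — fast to model."""
    return make_binary_dataset(
        FixtureSpec(n=60, n_active=12, n_continuous_desc=5, n_binary_desc=8,
                    effect=1.5, seed=7)
    )


@pytest.fixture(scope="session")
def small_plan(small_dataset):
    return build_plan(small_dataset.n, nsplits=2, nfolds=5)


@pytest.fixture(scope="session")
def small_store(small_dataset, small_plan):
    """Out-of-fold predictions for three cheap methods on the small fixture."""
    return run_repeated_cv(small_dataset, ["KNN", "Lasso", "RF"], small_plan)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
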