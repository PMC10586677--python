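import warnings

import numpy as np
import pytest

import omicstack as om

warnings.filterwarnings("ignore", message=".*did not converge.*")
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")
warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


# light hyperparameter grids: on the well-separated synthetic data used in
# the tests the models are insensitive to these knobs, so tuning over the
# full grids with 10 CV repeats would only burn time
LIGHT_GRIDS = {
    "SVM": {"C": [1.0, 10.0]},
    "RF": {"n_estimators": [200]},
    "FFNN": {"learning_rate_init": [1e-3]},
}


@pytest.fixture(scope="session")
def toy_study():
    return om.toy_fixture()


@pytest.fixture(scope="session")
def small_study():
    """A 300-sample, 4-cluster study shared by the slower integration tests."""
    cfg = om.GeneratorConfig(
        n_samples=300,
        k_true=4,
        n_features={"F1": 100, "F2": 50, "F3": 100, "F4": 30},
    )
    return om.generate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def small_stacked(small_study):
    _, stacked = om.preprocess_study(small_study.layers)
    return stacked
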