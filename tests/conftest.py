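import numpy as np
import pandas as pd
import pytest

from teahopper.synthetic import SyntheticConfig, simulate_herbivory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_predictors():
    """19-pot herbivory predictors at the default design, fixed seed."""
    cfg = SyntheticConfig(seed=42)
    predictors, truth = simulate_herbivory(cfg)
    return predictors, truth, cfg


def make_matrix(values, scale="ln"):
    from teahopper.preprocess import MetaboliteMatrix

    return MetaboliteMatrix(values=pd.DataFrame(values), scale=scale)
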