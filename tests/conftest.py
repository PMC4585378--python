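"""Shared fixtures: small synthetic studies and hand-built fold-change
matrices used across the suite."""

import numpy as np
import pandas as pd
import pytest

from healstage import GeneratorConfig, generate_blinded_tests, generate_study
from healstage.differential import FoldChangeMatrix, call_matrix
from healstage.simulate import DESIGN_TEST_LABELS

TIME_POINTS = [3, 10, 24, 48, 72, 168, 336, 504, 672]


def make_fc(log2fc: pd.DataFrame, fpkm_max=None, qvalues=None, min_fold=2.0) -> FoldChangeMatrix:
    """Build a FoldChangeMatrix from a log2fc frame with threshold calls."""
    calls = call_matrix(log2fc, min_fold=min_fold)
    if fpkm_max is None:
        fpkm_max = pd.Series(10.0, index=log2fc.index)
    return FoldChangeMatrix(log2fc, calls, fpkm_max, qvalues)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_features=500, effect_log2fc_range=(2.0, 4.0), seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def blinded(small_config):
    return generate_blinded_tests(small_config, list(DESIGN_TEST_LABELS), seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
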