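import warnings

import numpy as np
import pandas as pd
import pytest

import multimorbid as mm


@pytest.fixture(autouse=True)
def _quiet_constant_label_warnings():
    # tiny fixtures routinely produce constant labels / clone notices
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def toy_truth():
    return np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 0]])


@pytest.fixture
def toy_pred():
    return np.array([[1, 0, 0], [0, 1, 0], [1, 0, 0], [0, 0, 1]])


def make_dataset(X_cols: dict, Y_cols: dict) -> mm.MultiLabelDataset:
    return mm.MultiLabelDataset(pd.DataFrame(X_cols), pd.DataFrame(Y_cols))


@pytest.fixture
def tiny_dataset():
    return make_dataset(
        {"x1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
         "color": ["a", "b", "a", "b", "a", "b"]},
        {"y1": [1, 0, 1, 0, 1, 0], "y2": [0, 0, 1, 1, 0, 1]},
    )


def random_dataset(rng, n=40, L=4, p_feats=3):
    """Random small cohort where every label occurs at least once."""
    while True:
        Y = (rng.random((n, L)) < rng.uniform(0.1, 0.6, L)).astype(int)
        if (Y.sum(axis=0) > 0).all():
            break
    X = pd.DataFrame(rng.standard_normal((n, p_feats)),
                     columns=[f"x{j}" for j in range(p_feats)])
    return mm.MultiLabelDataset(X, pd.DataFrame(Y, columns=[f"y{j}" for j in range(L)]))


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    cfg = mm.calibrated_default_config()
    cfg.n = 400
    return mm.generate_cohort(cfg, seed=11)
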