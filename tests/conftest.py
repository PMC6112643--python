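import numpy as np
import pandas as pd
import pytest

from ehgkit.features import FeatureMatrix
from ehgkit import synthetic


@pytest.fixture(scope="session")
def short_record():
    """One 600-s term-archetype record + annotations (session-cached)."""
    cfg = synthetic.archetype_config("term_nonlabor", seed=101,
                                     duration_s=600.0)
    return synthetic.synth_record(cfg)


@pytest.fixture(scope="session")
def short_preterm_record():
    cfg = synthetic.archetype_config("preterm_like", seed=101,
                                     duration_s=600.0)
    return synthetic.synth_record(cfg)


def make_toy_matrix(n_per_class=50, n_features=10, informative=(2, 7),
                    shift=5.0, seed=11, columns=None):
    """Two-class Gaussian feature matrix with a few informative columns."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_features))
    sign = 1.0
    for j in informative:
        X[:n_per_class, j] += sign * shift
        sign = -sign
    cols = columns or [f"f{i}" for i in range(n_features)]
    y = pd.Series(["a"] * n_per_class + ["b"] * n_per_class, dtype=object)
    meta = pd.DataFrame({"record_id": ["r"] * n,
                         "interval_label": ["dummy"] * n,
                         "synthetic": [False] * n})
    return FeatureMatrix(pd.DataFrame(X, columns=cols), y, meta,
                         positive_label="a")


@pytest.fixture
def toy_matrix():
    return make_toy_matrix()
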