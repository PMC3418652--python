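import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import caseadapt as ca

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_library():
    """40 non-separable 2-D cases with a weak linear signal."""
    gen = np.random.default_rng(7)
    X = gen.standard_normal((40, 2))
    logits = 1.2 * X[:, 0] - 0.7 * X[:, 1]
    y = (gen.random(40) < 1 / (1 + np.exp(-logits))).astype(int)
    assert 0 < y.sum() < 40
    return ca.CaseLibrary.from_arrays(X, y, role="train")


@pytest.fixture(scope="session")
def toy_baseline(toy_library):
    return ca.BaselineLogistic().fit(toy_library.features, toy_library.labels)


@pytest.fixture(scope="session")
def bench_data():
    """Default locally varying benchmark: train/test/library + metadata."""
    return ca.generate(ca.SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def bench_baseline(bench_data):
    train, _, _, _ = bench_data
    return ca.BaselineLogistic().fit(train.features, train.labels)
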