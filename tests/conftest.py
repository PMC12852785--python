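import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ctx():
    from privimpute.fixedpoint import DealerContext

    return DealerContext(seed=7)


@pytest.fixture
def plain_engine():
    from privimpute.engine import PlainEngine

    return PlainEngine()


@pytest.fixture
def secure_engine():
    from privimpute.engine import SecureEngine
    from privimpute.fixedpoint import DealerContext

    return SecureEngine(DealerContext(seed=11))


def spd_matrix(rng, dim, eigenvalues=None):
    """Random symmetric positive-definite matrix with controlled spectrum."""
    eigenvalues = eigenvalues if eigenvalues is not None else rng.uniform(0.5, 4.0, dim)
    q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
    return q @ np.diag(eigenvalues) @ q.T
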