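import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ivfed import Interval, generate_synthetic

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=150,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def assert_interval(actual: Interval, lo: float, hi: float, tol: float = 1e-12) -> None:
    __tracebackhide__ = True
    assert abs(actual.lo - lo) <= tol, f"{actual} != [{lo}, {hi}] (lo)"
    assert abs(actual.hi - hi) <= tol, f"{actual} != [{lo}, {hi}] (hi)"


def random_interval(rng: np.random.Generator) -> Interval:
    lo = rng.uniform(0.0, 1.0)
    return Interval(lo, rng.uniform(lo, 1.0))


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic screening cohort (750 records, 249 positive)."""
    return generate_synthetic(seed=11)
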