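import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

from glasscoherence.design import (BlockProtocol, build_run_timeline,
                                   counterbalanced_orders)


@pytest.fixture
def protocol():
    return BlockProtocol()


@pytest.fixture
def timeline(protocol):
    orders = counterbalanced_orders(4, np.random.default_rng(7))
    return build_run_timeline(protocol, orders)


@pytest.fixture
def timelines12(protocol):
    rng = np.random.default_rng(11)
    return [build_run_timeline(protocol, counterbalanced_orders(4, rng))
            for _ in range(protocol.n_runs)]
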