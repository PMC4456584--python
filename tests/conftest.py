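import numpy as np
import pytest

from mcbalance.rate import CouplingMatrices, PointParams, RateNetwork
from mcbalance.spiking import SpikingParams, build_connectivity


@pytest.fixture(scope="session")
def ref_point() -> PointParams:
    """Reference within-point weights (q_ee 0.67, q_ei 1.7, q_ie 1, q_ii 2)."""
    return PointParams()


@pytest.fixture(scope="session")
def single_net(ref_point) -> RateNetwork:
    return RateNetwork(ref_point, K=1)


@pytest.fixture(scope="session")
def three_net(ref_point) -> RateNetwork:
    w = np.array([[0.0, 0.2, 0.02], [0.2, 0.0, 0.2], [0.02, 0.2, 0.0]])
    return RateNetwork(ref_point, CouplingMatrices(w, w.copy()))


@pytest.fixture(scope="session")
def tiny_spiking():
    """Very small spiking network (400 e / 100 i cells) for mechanics tests."""
    p = SpikingParams.scaled(scale=0.05)
    return p, build_connectivity(p, seed=7)
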