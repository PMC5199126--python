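import numpy as np
import pytest

from batchevol.deterministic import BatchProtocol, GrowthLaw

# empirical stressed phenotypes (minutes): WT and the three reconstructed
# arsenic-adaptation mutants
WT = dict(lag=804.8, doubling=162.3)
FPS1 = dict(lag=276.6, doubling=130.2)
ASK10 = dict(lag=503.3, doubling=134.6)
ACR3 = dict(lag=630.4, doubling=122.8)


@pytest.fixture
def protocol() -> BatchProtocol:
    return BatchProtocol(bottleneck=100_000, doublings_per_cycle=5, n_cycles=20)


@pytest.fixture
def wt_law() -> GrowthLaw:
    return GrowthLaw(WT["lag"], WT["doubling"], 99_999)


@pytest.fixture
def fps1_law() -> GrowthLaw:
    return GrowthLaw(FPS1["lag"], FPS1["doubling"], 1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
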