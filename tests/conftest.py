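import numpy as np
import pytest

from guancest.bmc import PerturbationRanges, SimTissue
from guancest.physics import AcquisitionScheme, PoolParams, WaterMTParams


@pytest.fixture(scope="session")
def scheme() -> AcquisitionScheme:
    return AcquisitionScheme.default_7t()


@pytest.fixture(scope="session")
def guan_pool() -> PoolParams:
    return PoolParams("guan", 2.0, fs=0.002, ksw=60.0, r2s=30.0)


@pytest.fixture(scope="session")
def water_params() -> WaterMTParams:
    return WaterMTParams(r1w=1.0 / 1.8, r2w=20.0, fm=0.0)


@pytest.fixture(scope="session")
def water_only_tissue() -> SimTissue:
    return SimTissue(r1w=1.0 / 1.8, r2w=20.0, pools=())


@pytest.fixture(scope="session")
def water_guan_tissue(guan_pool) -> SimTissue:
    return SimTissue(r1w=1.0 / 1.8, r2w=20.0, pools=(guan_pool,))


@pytest.fixture(scope="session")
def default_ranges() -> PerturbationRanges:
    return PerturbationRanges.default()
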