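import numpy as np
import pandas as pd
import pytest

from volesoc import DetectionParams, build_mask, make_trap_array
from volesoc.data import CaptureHistory
from volesoc.secrfit import HabitatMask


@pytest.fixture(scope="session")
def cross_traps():
    return make_trap_array("cross", 16, 15.0, grid_id="g1")


@pytest.fixture(scope="session")
def cross_mask(cross_traps):
    return build_mask(cross_traps, buffer=50.0, spacing=5.0)


@pytest.fixture(scope="session")
def coarse_mask(cross_traps):
    # ~200-point mask: enough for unbiased fits, fast enough for many of them
    return build_mask(cross_traps, buffer=50.0, spacing=10.0)


@pytest.fixture(scope="session")
def std_params():
    """The reference simulation condition used throughout the checks."""
    return DetectionParams(D=10.0, g0=0.2, sigma=15.0)


@pytest.fixture
def toy_fixture():
    """Smallest non-trivial likelihood case: 1 animal, 2 traps, 1 occasion,
    caught in trap 1, and a 4-point mask of 10 m pitch along the trap axis."""
    traps = make_trap_array("linear", 9, 30.0, grid_id="toy")
    # only the first two traps matter; rebuild with exactly two
    from volesoc.data import TrapArray
    traps = TrapArray(grid_id="toy", trap_ids=("t1", "t2"),
                      coords=np.array([[0.0, 0.0], [30.0, 0.0]]), shape="linear")
    mask = HabitatMask(points=np.array([[0.0, 0.0], [10.0, 0.0],
                                        [20.0, 0.0], [30.0, 0.0]]),
                       spacing=10.0, buffer=50.0)
    hist = CaptureHistory(
        session_id="toy", n_occasions=1,
        records=pd.DataFrame({"animal_id": ["a1"], "occasion": [1], "trap_id": ["t1"]}),
    )
    params = DetectionParams(D=10.0, g0=0.2, sigma=15.0)
    return params, hist, traps, mask
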