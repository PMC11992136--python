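import numpy as np
import pytest

from restingnorm.synthetic import SyntheticTruth, CLEAN_ARTIFACTS
from restingnorm.types import default_montage

GRID = np.arange(2.5, 45.0 + 0.25, 0.5)


@pytest.fixture(scope="session")
def montage32():
    """Small analysis montage (no exclusions) for signal-level tests."""
    return default_montage(32, 0)


@pytest.fixture(scope="session")
def montage24():
    return default_montage(24, 0)


@pytest.fixture(scope="session")
def grid():
    """The 0.5 Hz analysis frequency grid, 2.5-45 Hz."""
    return GRID.copy()


def make_truth(
    subject_id="S1",
    exponent=1.5,
    offset=0.5,
    peaks=((10.0, 0.5, 2.0),),
    coupling=(),
    artifacts=CLEAN_ARTIFACTS,
    seed=7,
    age=10.0,
    group="CTRL",
):
    return SyntheticTruth(
        subject_id=subject_id,
        group=group,
        age=age,
        sex="M",
        site=0,
        exponent=exponent,
        offset=offset,
        peaks=list(peaks),
        coupling=list(coupling),
        artifact_spec=artifacts,
        seed=seed,
    )


@pytest.fixture
def clean_truth():
    return make_truth()
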