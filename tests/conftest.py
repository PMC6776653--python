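import numpy as np
import pytest

from morpet.atlas import make_atlas
from morpet.cohort import CohortSpec, _reference_template
from morpet.kinetics import TimeActivityCurve, default_schedule


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def ref_tac(schedule):
    """Noiseless gamma-variate reference TAC on the 26-frame schedule."""
    vals = _reference_template(CohortSpec(), schedule)
    return TimeActivityCurve(schedule, vals, region_id="occipital", subject_id="ref")


@pytest.fixture(scope="session")
def atlas8():
    return make_atlas(8)


@pytest.fixture(scope="session")
def atlas20():
    return make_atlas(20)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
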