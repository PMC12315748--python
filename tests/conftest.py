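import numpy as np
import pytest

from tautrt import FrameSchedule, ScanMeta, frames_in_window, mk6240_frame_schedule
from tautrt.phantoms import ReferenceKinetics, reference_tac_model


@pytest.fixture(scope="session")
def schedule():
    return mk6240_frame_schedule()


@pytest.fixture(scope="session")
def window_schedule(schedule):
    """Only the four 5-min frames of the 90-110 min window (fast SUVR path)."""
    idx = frames_in_window(schedule, 90, 110)
    return FrameSchedule(schedule.starts[idx], schedule.ends[idx])


@pytest.fixture(scope="session")
def ref_kinetics():
    return ReferenceKinetics()


@pytest.fixture(scope="session")
def ref_tac(schedule, ref_kinetics):
    return reference_tac_model(ref_kinetics, schedule)


@pytest.fixture(scope="session")
def meta():
    return ScanMeta("sub-01", injected_dose_mbq=185.0, body_weight_kg=74.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
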