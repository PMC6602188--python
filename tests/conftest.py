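import numpy as np
import pytest

from hrvkit import load_hrv_table, load_patient_table
from hrvkit.rr_io import RRRecording


@pytest.fixture(scope="session")
def hrv_table():
    return load_hrv_table()


@pytest.fixture(scope="session")
def patient_table():
    return load_patient_table()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(intervals, **kw) -> RRRecording:
    return RRRecording(intervals=np.asarray(intervals, dtype=float), **kw)


@pytest.fixture
def constant_recording():
    return make_recording([800.0] * 400)
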