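import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from pulmorehab.regimen import FixedLevelTable, InteractiveLevelTable, WalkSession

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")


@pytest.fixture
def fixed_table():
    return FixedLevelTable()


@pytest.fixture
def interactive_table():
    return InteractiveLevelTable()


@pytest.fixture
def rng():
    return np.random.default_rng(20170501)


def make_session(distance=650.0, day=dt.date(2017, 5, 1), patient_id="P0001",
                 duration=1800.0, borg=None, samples=()):
    return WalkSession(
        patient_id=patient_id, session_date=day, distance=distance,
        duration=duration, borg=borg, samples=samples,
    )


@pytest.fixture
def session_factory():
    return make_session
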