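from datetime import datetime

import numpy as np
import pytest

from chronopheno.actogram import ActivityRecord

T0 = datetime(2024, 1, 1, 6, 0)


def make_record(counts, bin_minutes=5, subject="test", t0=T0) -> ActivityRecord:
    return ActivityRecord(subject_id=subject, t0=t0, bin_minutes=bin_minutes,
                          counts=np.asarray(counts))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
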