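import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from capselbow.cohort import Arm, CapsScores, Cohort, ParticipantRecord
from capselbow.synthetic import decompose_total

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def scores(total: int) -> CapsScores:
    """CapsScores with the item-weight cluster decomposition."""
    b, c, d, e = decompose_total(total)
    return CapsScores(total, b, c, d, e)


def record(pid: str, pre: int, post=None, fup=None, arm=Arm.ACTIVE,
           ) -> ParticipantRecord:
    return ParticipantRecord(
        participant_id=pid, arm=arm, pre=scores(pre),
        post=None if post is None else scores(post),
        fup=None if fup is None else scores(fup))


@pytest.fixture
def toy_cohort() -> Cohort:
    """Four active subjects with (post/pre, fup/pre) ratios
    (0.5,0.4), (0.6,0.7), (0.8,0.7), (0.9,1.0) on a baseline of 40."""
    return Cohort(records=[
        record("P1", 40, 20, 16),
        record("P2", 40, 24, 28),
        record("P3", 40, 32, 28),
        record("P4", 40, 36, 40),
    ])


@pytest.fixture
def two_arm_cohort() -> Cohort:
    """Small two-arm cohort with complete assessments."""
    recs = [record(f"A{i}", 40 + i, 26 + 2 * i, 20 + 2 * i) for i in range(6)]
    recs += [record(f"S{i}", 42 + i, 41 + i, 42 + i, arm=Arm.SHAM)
             for i in range(4)]
    return Cohort(records=recs)
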