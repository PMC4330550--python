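import numpy as np
import pytest

from revlearn import BehavioralRecord, TaskConfig


@pytest.fixture
def default_config() -> TaskConfig:
    return TaskConfig()


def make_record(choices, outcomes, missed=None, run=None, subject_id="sub-01", group="test"):
    """Build a BehavioralRecord directly from choice/outcome sequences."""
    choices = np.asarray(choices)
    n = len(choices)
    if missed is None:
        missed = np.zeros(n, dtype=bool)
    if run is None:
        run = np.zeros(n, dtype=int)
    return BehavioralRecord(
        subject_id=subject_id,
        group=group,
        run=np.asarray(run),
        choice=choices,
        correct_stimulus=np.zeros(n, dtype=int),
        outcome=np.asarray(outcomes),
        missed=np.asarray(missed),
        reversal_after=np.zeros(n, dtype=bool),
    )


@pytest.fixture
def record_factory():
    return make_record
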