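"""Shared fixtures: tiny synthetic cohorts and model configs."""

import datetime as dt

import pytest

from hibehrt.records import (PatientHistory, RecordEvent, Vocabulary,
                             default_schemes)
from hibehrt.synthetic import SyntheticCohortParams, generate


@pytest.fixture(scope="session")
def schemes():
    return default_schemes()


@pytest.fixture
def simple_history():
    """Three visits over two calendar dates plus an out-of-range reading."""
    birth = dt.date(1960, 5, 1)
    events = [
        RecordEvent(dt.date(2005, 1, 10), "diagnosis", code="DIAG_0001"),
        RecordEvent(dt.date(2005, 1, 10), "systolic_bp", value=92.0),
        RecordEvent(dt.date(2006, 3, 4), "medication", code="MED_0007"),
        RecordEvent(dt.date(2006, 3, 4), "systolic_bp", value=79.9),  # dropped
        RecordEvent(dt.date(2008, 7, 1), "diagnosis", code="DIAG_0042"),
    ]
    return PatientHistory("P1", birth, events)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small deep-signal cohort shared by slower tests."""
    params = SyntheticCohortParams(n_patients=40, seed=11)
    histories, truths = generate(params)
    return params, histories, truths


@pytest.fixture(scope="session")
def tiny_vocab(tiny_cohort):
    _, histories, _ = tiny_cohort
    return Vocabulary.from_histories(histories)
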