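from datetime import datetime, timedelta

import pytest

from ctalert import replay
from ctalert.core import EventKind, RecruitmentEvent, RecruitmentState
from ctalert.datasets import reference_event_log


@pytest.fixture(scope="session")
def reference_log():
    """The packaged 25-practice reference study as an event log."""
    return reference_event_log()


@pytest.fixture(scope="session")
def reference_registry(reference_log):
    return replay(reference_log)


def make_events(study_id, kinds, practice_id="p1", sex="F", band="F70-79",
                start=None, payloads=None):
    """Build a same-day event sequence for one record (test helper)."""
    start = start or datetime(2008, 1, 7, 9, 0)
    payloads = payloads or {}
    return [
        RecruitmentEvent(
            timestamp=start + timedelta(minutes=i),
            practice_id=practice_id,
            study_id=study_id,
            kind=EventKind(kind),
            sex=sex,
            age_band=band,
            payload=payloads.get(i),
        )
        for i, kind in enumerate(kinds)
    ]


#: kind sequences that land a record in each final state
SEQUENCES = {
    RecruitmentState.OPEN: ["epr_open", "click_off"],
    RecruitmentState.SURVEY_IN_PROGRESS: [
        "epr_open", "contact", "consent", "survey_start", "survey_interrupt"
    ],
    RecruitmentState.EXCLUDED: ["epr_open", "exclude"],
    RecruitmentState.REFUSED: ["epr_open", "contact", "refuse"],
    RecruitmentState.ENROLLED: [
        "epr_open", "contact", "consent", "survey_start", "survey_complete"
    ],
    RecruitmentState.DECEASED: ["epr_open", "deceased_noted"],
}


def events_for_state(study_id, state, **kwargs):
    kinds = SEQUENCES[state]
    payloads = {}
    if state is RecruitmentState.EXCLUDED:
        payloads = {1: {"reason": "other"}}
    return make_events(study_id, kinds, payloads=payloads, **kwargs)
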