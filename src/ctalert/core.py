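"""Eligibility rule, pseudonymisation, and the recruitment state machine.

A clinical trial alert (CTA) engine watches electronic patient records
(EPRs): whenever the chart of a demographically eligible patient is opened,
an on-screen reminder prompts the practice staff to review eligibility,
contact the patient, and — if the patient consents — run the study survey
on the spot.  Every action is appended to a pseudonymised event log that a
study centre can replay in real time.

This module holds the pieces that define the recruitment *protocol*:

* :func:`net_sample_rule` — the demographic inclusion rule (women 60+,
  men 70+, completed years at the date of the EPR opening);
* :func:`pseudonymize` — a keyed one-way digest mapping the practice-local
  patient id to a study id re-identifiable only with the practice key;
* :func:`apply_event` / :func:`replay` — the state machine that folds a
  recruitment event stream into per-patient recruitment states.
"""

from __future__ import annotations

import base64
import enum
import hashlib
import hmac
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Mapping, Optional


class CTAError(Exception):
    """Base class for recruitment-engine errors."""


class InvalidInputError(CTAError, ValueError):
    """An argument violates an operation's precondition."""


class ProtocolError(CTAError):
    """An event stream violates the recruitment protocol."""


class TerminalStateError(ProtocolError):
    """A recruitment event was applied to an absorbing state."""


class RecruitmentState(enum.Enum):
    OPEN = "open"
    SURVEY_IN_PROGRESS = "survey_in_progress"
    EXCLUDED = "excluded"
    REFUSED = "refused"
    ENROLLED = "enrolled"
    DECEASED = "deceased"


#: States that permit no further recruitment activity.  An EPR of a
#: finalized patient may still be opened (no reminder fires), but any other
#: event is a protocol violation.
ABSORBING_STATES = frozenset(
    {
        RecruitmentState.EXCLUDED,
        RecruitmentState.REFUSED,
        RecruitmentState.ENROLLED,
        RecruitmentState.DECEASED,
    }
)

#: States in which the on-screen reminder is (re-)shown.  Ignored reminders
#: and unfinished surveys both count as "open" business.
ALERTABLE_STATES = frozenset(
    {RecruitmentState.OPEN, RecruitmentState.SURVEY_IN_PROGRESS}
)


class EventKind(str, enum.Enum):
    EPR_OPEN = "epr_open"
    CLICK_OFF = "click_off"
    EXCLUDE = "exclude"
    CONTACT = "contact"
    REFUSE = "refuse"
    CONSENT = "consent"
    SURVEY_START = "survey_start"
    SURVEY_INTERRUPT = "survey_interrupt"
    SURVEY_COMPLETE = "survey_complete"
    DECEASED_NOTED = "deceased_noted"


EXCLUSION_REASONS = (
    "psychiatric_disorder",
    "language_barrier",
    "not_physically_present",
    "other",
)

#: The five demographic strata of the study population: sex crossed with
#: completed-age band at identification.  Women enter at 60, men at 70.
AGE_BANDS = ("F60-69", "F70-79", "F80+", "M70-79", "M80+")


@dataclass(frozen=True)
class PatientRecord:
    """An identified person in a practice panel (practice-side, not pseudonymised)."""

    internal_id: str
    practice_id: str
    sex: str  # "F" or "M"
    birth_date: date
    deceased: bool = False


@dataclass(frozen=True)
class RecruitmentEvent:
    """One timestamped recruitment action on a pseudonymised record."""

    timestamp: datetime
    practice_id: str
    study_id: str
    kind: EventKind
    sex: str
    age_band: str
    payload: Optional[dict] = None
    recorded: bool = True  # False while the practice software was down

    @property
    def exclusion_reason(self) -> Optional[str]:
        if self.payload:
            return self.payload.get("reason")
        return None


@dataclass
class StudyRecord:
    """The pseudonymised registry entry for one identified patient.

    Carries no practice-internal id and no full birth date — only the sex
    and completed-age band needed for selection-bias monitoring.
    """

    study_id: str
    practice_id: str
    sex: str
    age_band: str
    state: RecruitmentState = RecruitmentState.OPEN
    events: list = field(default_factory=list)
    exclusion_reason: Optional[str] = None
    # protocol bookkeeping for order validation during replay
    _contacted: bool = field(default=False, repr=False)
    _consented: bool = field(default=False, repr=False)


def completed_age(birth_date: date, on: date) -> int:
    """Whole years elapsed between ``birth_date`` and ``on``."""
    if on < birth_date:
        raise InvalidInputError(
            f"reference date {on} precedes birth date {birth_date}"
        )
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def net_sample_rule(sex: str, birth_date: date, reference_date: date) -> bool:
    """Demographic inclusion rule: women 60 and older, men 70 and older.

    Age is the completed age at ``reference_date`` — normally the date the
    EPR is opened, so patients crossing a threshold mid-study enter the net
    sample at their next visit.
    """
    if sex not in ("F", "M"):
        raise InvalidInputError(f"sex must be 'F' or 'M', got {sex!r}")
    age = completed_age(birth_date, reference_date)
    return age >= 60 if sex == "F" else age >= 70


def age_band(sex: str, birth_date: date, on: date) -> Optional[str]:
    """Stratum label for an eligible patient, or ``None`` below threshold."""
    age = completed_age(birth_date, on)
    if sex == "F":
        if age < 60:
            return None
        if age < 70:
            return "F60-69"
        return "F70-79" if age < 80 else "F80+"
    if sex == "M":
        if age < 70:
            return None
        return "M70-79" if age < 80 else "M80+"
    raise InvalidInputError(f"sex must be 'F' or 'M', got {sex!r}")


def pseudonymize(internal_id: str, practice_secret: str) -> str:
    """Map a practice-internal patient id to an irreversible study id.

    The study id is a truncated HMAC-SHA256 of the internal id under a
    per-practice secret, rendered in base32.  It is deterministic for a
    fixed (id, secret) pair, collision-free in practice (80 bits), and
    reveals nothing about the internal id; re-identification requires the
    practice-local key map.
    """
    if not internal_id:
        raise InvalidInputError("internal_id must be non-empty")
    if not practice_secret:
        raise InvalidInputError("practice_secret must be non-empty")
    digest = hmac.new(
        practice_secret.encode("utf-8"), internal_id.encode("utf-8"), hashlib.sha256
    ).digest()
    token = base64.b32encode(digest).decode("ascii")[:16]
    return "S" + token


def _kind_of(event) -> EventKind:
    if isinstance(event, RecruitmentEvent):
        return event.kind
    return EventKind(event)


# (state, kind) -> next state for every legal non-error transition.
_TRANSITIONS: Mapping[tuple, RecruitmentState] = {
    (RecruitmentState.OPEN, EventKind.EPR_OPEN): RecruitmentState.OPEN,
    (RecruitmentState.OPEN, EventKind.CLICK_OFF): RecruitmentState.OPEN,
    (RecruitmentState.OPEN, EventKind.EXCLUDE): RecruitmentState.EXCLUDED,
    (RecruitmentState.OPEN, EventKind.CONTACT): RecruitmentState.OPEN,
    (RecruitmentState.OPEN, EventKind.REFUSE): RecruitmentState.REFUSED,
    (RecruitmentState.OPEN, EventKind.CONSENT): RecruitmentState.OPEN,
    (RecruitmentState.OPEN, EventKind.SURVEY_START): RecruitmentState.SURVEY_IN_PROGRESS,
    (RecruitmentState.OPEN, EventKind.DECEASED_NOTED): RecruitmentState.DECEASED,
    (RecruitmentState.SURVEY_IN_PROGRESS, EventKind.EPR_OPEN): RecruitmentState.SURVEY_IN_PROGRESS,
    (RecruitmentState.SURVEY_IN_PROGRESS, EventKind.CLICK_OFF): RecruitmentState.SURVEY_IN_PROGRESS,
    (RecruitmentState.SURVEY_IN_PROGRESS, EventKind.SURVEY_INTERRUPT): RecruitmentState.SURVEY_IN_PROGRESS,
    (RecruitmentState.SURVEY_IN_PROGRESS, EventKind.SURVEY_COMPLETE): RecruitmentState.ENROLLED,
    (RecruitmentState.SURVEY_IN_PROGRESS, EventKind.DECEASED_NOTED): RecruitmentState.DECEASED,
}


def apply_event(state: RecruitmentState, event) -> RecruitmentState:
    """One step of the recruitment state machine.

    ``event`` may be a :class:`RecruitmentEvent`, an :class:`EventKind`, or
    a kind string.  Absorbing states accept only ``epr_open`` (the chart
    may still be opened; no reminder fires) and reject everything else.
    """
    kind = _kind_of(event)
    if state in ABSORBING_STATES:
        if kind is EventKind.EPR_OPEN:
            return state
        raise TerminalStateError(
            f"event {kind.value!r} on absorbing state {state.value!r}"
        )
    if kind is EventKind.EXCLUDE and isinstance(event, RecruitmentEvent):
        reason = event.exclusion_reason
        if reason not in EXCLUSION_REASONS:
            raise ProtocolError(
                f"exclude event must carry a reason in {EXCLUSION_REASONS}, got {reason!r}"
            )
    try:
        return _TRANSITIONS[(state, kind)]
    except KeyError:
        raise ProtocolError(
            f"event {kind.value!r} is out of order in state {state.value!r}"
        ) from None


def fold_record(record: StudyRecord, event: RecruitmentEvent) -> StudyRecord:
    """Apply one event to a registry record, enforcing ordering rules.

    Beyond the pure state transition this checks the visit protocol:
    any non-``epr_open`` event must follow an ``epr_open`` for the same
    record on the same calendar day, refusal and consent require a prior
    contact, and a survey can only start after consent.
    """
    kind = event.kind
    if kind is not EventKind.EPR_OPEN:
        last_open = next(
            (e for e in reversed(record.events) if e.kind is EventKind.EPR_OPEN),
            None,
        )
        if last_open is None or last_open.timestamp.date() != event.timestamp.date():
            raise ProtocolError(
                f"{kind.value!r} for {record.study_id} without an epr_open "
                "on the same calendar day"
            )
    if kind in (EventKind.REFUSE, EventKind.CONSENT) and not record._contacted:
        raise ProtocolError(
            f"{kind.value!r} for {record.study_id} without a prior contact"
        )
    if kind is EventKind.SURVEY_START and not record._consented:
        raise ProtocolError(
            f"survey_start for {record.study_id} without a prior consent"
        )
    record.state = apply_event(record.state, event)
    if kind is EventKind.CONTACT:
        record._contacted = True
    elif kind is EventKind.CONSENT:
        record._consented = True
    elif kind is EventKind.EXCLUDE:
        record.exclusion_reason = event.exclusion_reason
    record.events.append(event)
    return record


def replay(events: Iterable[RecruitmentEvent]) -> dict:
    """Fold an event stream into a registry: ``{study_id: StudyRecord}``.

    The stream must be time-ordered within each practice; the first event
    for each study id must be an ``epr_open``.  Replay is deterministic:
    two replays of the same log yield identical registries.
    """
    registry: dict[str, StudyRecord] = {}
    last_ts: dict[str, datetime] = {}
    for event in events:
        prev = last_ts.get(event.practice_id)
        if prev is not None and event.timestamp < prev:
            raise ProtocolError(
                f"events out of time order in practice {event.practice_id}"
            )
        last_ts[event.practice_id] = event.timestamp
        record = registry.get(event.study_id)
        if record is None:
            if event.kind is not EventKind.EPR_OPEN:
                raise ProtocolError(
                    f"first event for {event.study_id} is {event.kind.value!r}, "
                    "expected epr_open"
                )
            record = StudyRecord(
                study_id=event.study_id,
                practice_id=event.practice_id,
                sex=event.sex,
                age_band=event.age_band,
            )
            registry[event.study_id] = record
        fold_record(record, event)
    return registry


def should_alert(record: StudyRecord, suppression=None) -> bool:
    """Whether the on-screen reminder fires when this patient's EPR opens.

    The reminder keeps reappearing for every open case (including
    unfinished surveys) until the recruitment process is finalized —
    unless an adaptive suppression policy currently mutes the record's
    demographic stratum.
    """
    if record.state not in ALERTABLE_STATES:
        return False
    if suppression is not None and record.age_band in suppression.suppressed_strata:
        return False
    return True
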