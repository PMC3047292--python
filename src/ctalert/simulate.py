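"""Synthetic general-practice simulator.

Generates practice panels, per-patient visit (EPR-open) streams, software
downtime, and probabilistic staff recruitment behaviour, producing event
logs that replay legally through the recruitment state machine.  This is
the test bed for the whole pipeline: the funnel, the bias monitor and the
adaptive suppression policy can all be exercised against a ground truth
that no real electronic-patient-record system would expose.

The generative model, per practice:

* **Panel** — ``panel_size`` eligible patients drawn i.i.d. from a
  probability vector over the five sex x age-band strata, with birth dates
  uniform within each band at study start; a small fraction is deceased
  (their charts may still be opened).
* **Visits** — each patient's EPR-open count over the study is Poisson
  with mean ``visit_rate x study_months``, times uniform in the study
  window; each open is flagged physically-present with probability
  ``1 - not_present_prob``.  Opens falling in a downtime window are marked
  unrecorded: the registry never sees them, the oracle sidecar does.
* **Staff** — at every recorded open of an alertable record the staff
  responds with probability ``p_respond`` (times an optional per-stratum
  multiplier, the bias injector), otherwise clicks the reminder off.
  Responses branch to exclusion or contact; contacts branch to refusal or
  consent + survey; surveys either complete on the spot or are interrupted
  and completed at the patient's next recorded visit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AGE_BANDS,
    EventKind,
    InvalidInputError,
    PatientRecord,
    RecruitmentEvent,
    RecruitmentState,
    StudyRecord,
    age_band,
    net_sample_rule,
    pseudonymize,
    should_alert,
)
from .bias import StrataTable, SuppressionPolicy, update_suppression

#: Net-sample demography of the reference study (shares of the five
#: strata among 16,067 identified patients): 72% women, and within each
#: sex the age mix skews old.  Used as the default panel demography.
REFERENCE_DEMOGRAPHY = {
    "F60-69": 3378 / 16067,
    "F70-79": 3749 / 16067,
    "F80+": 4447 / 16067,
    "M70-79": 2536 / 16067,
    "M80+": 1957 / 16067,
}

# Age span (completed years at study start) each band draws from.  The
# open-ended bands are capped at 95; older patients are rare in the
# consulting population.
_BAND_AGE_RANGE = {
    "F60-69": (60.0, 70.0),
    "F70-79": (70.0, 80.0),
    "F80+": (80.0, 95.0),
    "M70-79": (70.0, 80.0),
    "M80+": (80.0, 95.0),
}


@dataclass(frozen=True)
class PracticeConfig:
    """One simulated practice: panel, visit process, downtime."""

    practice_id: str
    panel_size: int
    demography: Mapping[str, float] = field(
        default_factory=lambda: dict(REFERENCE_DEMOGRAPHY)
    )
    visit_rate: float = 0.6          # EPR opens per patient per month
    not_present_prob: float = 0.25   # open without the patient in the practice
    downtime_windows: Sequence[tuple] = ()   # [start, end) date pairs
    study_months: int = 12
    study_start: date = date(2007, 11, 1)
    deceased_frac: float = 0.0015

    def __post_init__(self):
        if self.panel_size < 0:
            raise InvalidInputError("panel_size must be non-negative")
        if self.visit_rate < 0:
            raise InvalidInputError("visit_rate must be non-negative")
        total = sum(self.demography.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError(
                f"demography must sum to 1 (got {total!r})"
            )
        if set(self.demography) - set(AGE_BANDS):
            raise InvalidInputError("demography keys must be the five strata")

    @property
    def study_end(self) -> date:
        return _add_months(self.study_start, self.study_months)


@dataclass(frozen=True)
class StaffBehaviour:
    """Probabilistic staff response model.

    Defaults are calibrated so that, with the default visit rate of 0.6
    opens per patient-month over 12 months, roughly 32% of identified
    patients get reviewed, 63% of reviews end in exclusion (reviews of
    patients not physically present always exclude, so the conditional
    probability for present patients is lower), 20% of contacted patients
    refuse, and a few percent of started surveys are interrupted — the
    proportions observed in the reference study.
    """

    p_respond: float = 0.054
    p_exclude_given_respond: float = 0.51
    p_refuse_given_contact: float = 0.20
    p_interrupt_given_start: float = 0.05
    contact_multipliers: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for name in (
            "p_respond",
            "p_exclude_given_respond",
            "p_refuse_given_contact",
            "p_interrupt_given_start",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1], got {p}")
        if any(m < 0 for m in self.contact_multipliers.values()):
            raise InvalidInputError("contact multipliers must be non-negative")


def _add_months(d: date, months: int) -> date:
    month = d.month - 1 + months
    year = d.year + month // 12
    month = month % 12 + 1
    day = min(d.day, 28)
    return date(year, month, day)


def practice_rng(seed: int, practice_id: str) -> np.random.Generator:
    """Per-practice random stream keyed by (run seed, practice id)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(practice_id.encode("utf-8"))])
    )


def generate_panel(config: PracticeConfig, seed: int) -> list:
    """Draw a practice panel of eligible patients from the configured demography."""
    rng = practice_rng(seed, config.practice_id)
    bands = list(config.demography.keys())
    probs = np.array([config.demography[b] for b in bands], dtype=float)
    if config.panel_size == 0:
        return []
    choices = rng.choice(len(bands), size=config.panel_size, p=probs)
    deceased = rng.random(config.panel_size) < config.deceased_frac
    panel = []
    for i, (bi, dead) in enumerate(zip(choices, deceased)):
        band = bands[bi]
        lo, hi = _BAND_AGE_RANGE[band]
        age_years = rng.uniform(lo, hi)
        birth = config.study_start - timedelta(days=age_years * 365.2425 + 1)
        panel.append(
            PatientRecord(
                internal_id=f"{config.practice_id}-P{i:06d}",
                practice_id=config.practice_id,
                sex=band[0],
                birth_date=birth,
                deceased=bool(dead),
            )
        )
    return panel


def _in_downtime(ts: datetime, windows) -> bool:
    d = ts.date()
    return any(start <= d < end for start, end in windows)


def simulate_visits(
    panel: Sequence[PatientRecord],
    config: PracticeConfig,
    seed: int,
    practice_secret: Optional[str] = None,
) -> list:
    """Generate the time-ordered stream of EPR-open events for one practice.

    Per patient the number of opens is Poisson(``visit_rate x
    study_months``); times are uniform over the study window.  Each open
    carries a ``physically_present`` flag and is marked ``recorded=False``
    when it falls inside a downtime window (the practice software could
    neither alert nor transmit during downtime).

    Only opens at which the patient satisfies the demographic inclusion
    rule generate identification events; panels built by
    :func:`generate_panel` are eligible throughout.
    """
    if config.study_months <= 0:
        raise InvalidInputError("study_months must be positive")
    rng = practice_rng(seed + 1, config.practice_id)
    secret = practice_secret or f"secret-{seed}-{config.practice_id}"
    start = datetime.combine(config.study_start, time(8, 0))
    span_days = (config.study_end - config.study_start).days
    events = []
    mean_visits = config.visit_rate * config.study_months
    for patient in panel:
        n_visits = rng.poisson(mean_visits)
        if n_visits == 0:
            continue
        study_id = pseudonymize(patient.internal_id, secret)
        offsets = np.sort(rng.uniform(0.0, span_days, size=n_visits))
        present = rng.random(n_visits) >= config.not_present_prob
        for off, pres in zip(offsets, present):
            ts = start + timedelta(days=float(off) // 1, minutes=float(off) % 1 * 540)
            if not net_sample_rule(patient.sex, patient.birth_date, ts.date()):
                continue
            band = age_band(patient.sex, patient.birth_date, ts.date())
            events.append(
                RecruitmentEvent(
                    timestamp=ts,
                    practice_id=config.practice_id,
                    study_id=study_id,
                    kind=EventKind.EPR_OPEN,
                    sex=patient.sex,
                    age_band=band,
                    payload={"physically_present": bool(pres)},
                    recorded=not _in_downtime(ts, config.downtime_windows),
                )
            )
    events.sort(key=lambda e: e.timestamp)
    return events


def simulate_staff(
    epr_open_events: Sequence[RecruitmentEvent],
    behaviour: StaffBehaviour,
    deceased_ids: Optional[Iterable[str]] = None,
    suppression: Optional[SuppressionPolicy] = None,
) -> list:
    """Play staff behaviour over a visit stream; return the full event log.

    Walks the recorded EPR opens in time order, keeping per-record
    recruitment state; at each open of an alertable record the staff either
    responds (exclude / contact / consent+survey per the configured
    probabilities) or clicks the reminder off.  Interrupted surveys resume
    and complete at the patient's next recorded visit.  Unrecorded
    (downtime) opens pass through untouched: no alert fired.

    When a :class:`SuppressionPolicy` is given, the policy is re-evaluated
    after every enrolment against the accruing identified-vs-enrolled
    demography, and opens in suppressed strata fire no alert.

    The returned log (recorded events only, plus the unrecorded opens kept
    for the oracle) replays without protocol errors.
    """
    rng = np.random.default_rng(behaviour.seed)
    deceased_ids = set(deceased_ids or ())
    states: dict[str, RecruitmentState] = {}
    records: dict[str, StudyRecord] = {}
    policy = suppression
    # accruing demography for adaptive suppression
    net_acc = {b: 0 for b in AGE_BANDS}
    enr_acc = {b: 0 for b in AGE_BANDS}
    out = []

    def follow(base, kind, minutes, payload=None):
        return RecruitmentEvent(
            timestamp=base.timestamp + timedelta(minutes=minutes),
            practice_id=base.practice_id,
            study_id=base.study_id,
            kind=kind,
            sex=base.sex,
            age_band=base.age_band,
            payload=payload,
        )

    def refresh_policy():
        counts = pd.DataFrame(
            {
                "enrolled": [enr_acc[b] for b in AGE_BANDS],
                "other": [net_acc[b] - enr_acc[b] for b in AGE_BANDS],
            },
            index=list(AGE_BANDS),
        )
        counts = counts.rename(columns={"other": "open"})
        return update_suppression(policy, StrataTable.from_counts(counts))

    K = EventKind
    for event in epr_open_events:
        out.append(event)
        if not event.recorded:
            continue  # software down: no alert, nothing registered
        sid = event.study_id
        if sid not in states:
            states[sid] = RecruitmentState.OPEN
            records[sid] = StudyRecord(
                study_id=sid,
                practice_id=event.practice_id,
                sex=event.sex,
                age_band=event.age_band,
            )
            net_acc[event.age_band] += 1
        state = states[sid]
        record = records[sid]
        record.state = state
        if not should_alert(record, policy):
            continue
        present = bool(event.payload and event.payload.get("physically_present"))
        if state is RecruitmentState.SURVEY_IN_PROGRESS:
            # unfinished survey: completed at this next visit
            out.append(follow(event, K.SURVEY_COMPLETE, 10))
            states[sid] = RecruitmentState.ENROLLED
            enr_acc[event.age_band] += 1
            if policy is not None:
                policy = refresh_policy()
            continue
        multiplier = behaviour.contact_multipliers.get(event.age_band, 1.0)
        p = min(1.0, behaviour.p_respond * multiplier)
        if rng.random() >= p:
            out.append(follow(event, K.CLICK_OFF, 1))
            continue
        # staff responds: eligibility review
        if sid in deceased_ids:
            out.append(follow(event, K.DECEASED_NOTED, 1))
            states[sid] = RecruitmentState.DECEASED
            continue
        if not present:
            # patient not in the practice: review can only exclude
            out.append(
                follow(event, K.EXCLUDE, 1, {"reason": "not_physically_present"})
            )
            states[sid] = RecruitmentState.EXCLUDED
            continue
        if rng.random() < behaviour.p_exclude_given_respond:
            reason = rng.choice(("psychiatric_disorder", "language_barrier", "other"))
            out.append(follow(event, K.EXCLUDE, 1, {"reason": str(reason)}))
            states[sid] = RecruitmentState.EXCLUDED
            continue
        out.append(follow(event, K.CONTACT, 2))
        if rng.random() < behaviour.p_refuse_given_contact:
            out.append(follow(event, K.REFUSE, 3))
            states[sid] = RecruitmentState.REFUSED
            continue
        out.append(follow(event, K.CONSENT, 4))
        out.append(follow(event, K.SURVEY_START, 5))
        if rng.random() < behaviour.p_interrupt_given_start:
            out.append(follow(event, K.SURVEY_INTERRUPT, 9))
            states[sid] = RecruitmentState.SURVEY_IN_PROGRESS
        else:
            out.append(follow(event, K.SURVEY_COMPLETE, 15))
            states[sid] = RecruitmentState.ENROLLED
            enr_acc[event.age_band] += 1
            if policy is not None:
                policy = refresh_policy()
    out.sort(key=lambda e: (e.practice_id, e.timestamp))
    return out


@dataclass
class SimulationResult:
    """Everything one simulated practice run produces."""

    all_events: list                 # full log incl. unrecorded opens
    panel: list
    key_map: dict                    # study_id -> internal_id (practice-side)

    @property
    def registry_events(self) -> list:
        """What the study centre receives (downtime opens missing)."""
        return [e for e in self.all_events if e.recorded]

    @property
    def registry_ids(self) -> set:
        return {e.study_id for e in self.registry_events}

    @property
    def oracle_ids(self) -> set:
        """Eligible patients seen in the window, per full panel query."""
        return {e.study_id for e in self.all_events if e.kind is EventKind.EPR_OPEN}


def simulate_practice(
    config: PracticeConfig,
    behaviour: StaffBehaviour,
    seed: int,
    suppression: Optional[SuppressionPolicy] = None,
) -> SimulationResult:
    """Panel + visits + staff for one practice, reproducible from ``seed``."""
    panel = generate_panel(config, seed)
    secret = f"secret-{seed}-{config.practice_id}"
    visits = simulate_visits(panel, config, seed, practice_secret=secret)
    key_map = {
        pseudonymize(p.internal_id, secret): p.internal_id for p in panel
    }
    deceased = {
        pseudonymize(p.internal_id, secret) for p in panel if p.deceased
    }
    behaviour = StaffBehaviour(
        **{
            **behaviour.__dict__,
            "seed": int(
                np.random.SeedSequence(
                    [seed + 2, zlib.crc32(config.practice_id.encode())]
                ).generate_state(1)[0]
                % (2**31)
            ),
        }
    )
    log = simulate_staff(visits, behaviour, deceased_ids=deceased,
                         suppression=suppression)
    return SimulationResult(all_events=log, panel=panel, key_map=key_map)
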