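"""Built-in reference dataset: a 25-practice, 12-month recruitment study.

The package ships the published accounting of a German general-practice
osteoporosis risk survey in which a clinical trial alert tool identified a
net sample of 16,067 patients (women 60+, men 70+) across 25 practices and
the practice staff enrolled 1,526 of them.  Three fixtures are provided:

* :data:`REFERENCE_FUNNEL` — the study-wide recruitment funnel;
* :data:`REFERENCE_PRACTICES` — per-practice net sample and enrolment
  (the enrolment-rate / target-achievement table);
* :data:`REFERENCE_STRATA` — stage x demographic-stratum counts
  (the sex-and-age selection-bias table).

The stratum counts are integer reconstructions from the published column
percentages (largest-remainder apportionment of each stage total); every
reconstructed count reproduces its printed share to one decimal.  One
printed cell pair — the men's "open" column age split — is inconsistent
with the net-sample column under funnel conservation and appears transposed
in print; the fixture stores the conservation-consistent orientation
(58.5% aged 70-79, 41.5% aged 80+).

:func:`reference_event_log` expands these counts into a synthetic but fully
protocol-legal event log (one minimal event sequence per patient) whose
replay reproduces all three fixtures exactly.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta

import pandas as pd

from .core import AGE_BANDS, EventKind, RecruitmentEvent, RecruitmentState

#: Study-wide funnel: every identified patient is counted once by final
#: state.  "open" includes the 43 consented-but-unfinished surveys;
#: "excluded" includes the 22 EPRs opened after the patient had died.
REFERENCE_FUNNEL = {
    "identified": 16067,
    "open": 10906,
    "excluded": 3248,
    "contacted": 1913,
    "refused": 387,
    "enrolled": 1526,
    "deceased_subcount": 22,
    "in_progress_subcount": 43,
}

#: Per-practice target: enrol 200 patients in 12 months.
REFERENCE_TARGET = 200

#: Practices with fewer than this many identified EPRs count as "small".
REFERENCE_SIZE_THRESHOLD = 600

#: (practice_id, net_sample, enrolled) for the 25 analysed practices.
REFERENCE_PRACTICES = (
    ("1", 162, 14),
    ("2", 255, 31),
    ("3", 256, 30),
    ("4", 334, 87),
    ("5", 350, 82),
    ("6", 386, 71),
    ("7", 390, 41),
    ("8", 407, 53),
    ("9", 454, 115),
    ("10", 455, 93),
    ("11", 505, 4),
    ("12", 511, 78),
    ("13", 596, 54),
    ("14", 616, 99),
    ("15", 636, 26),
    ("16", 689, 11),
    ("17", 801, 133),
    ("18", 808, 31),
    ("19", 901, 41),
    ("20", 905, 9),
    ("21", 986, 202),
    ("22", 1021, 54),
    ("23", 1150, 85),
    ("24", 1177, 55),
    ("25", 1316, 27),
)

# Outcome-stage counts per stratum, reconstructed from the printed column
# percentages; "excluded" totals 3,248 and includes the deceased sub-arm.
_STAGE_STRATUM_COUNTS = {
    #             F60-69  F70-79  F80+   M70-79  M80+
    "open":      (2435,   2520,   2735,  1881,   1335),
    "excluded":  (390,    611,    1376,  385,    486),
    "refused":   (87,     99,     81,    68,     52),
    "enrolled":  (466,    519,    255,   202,    84),
}

# Sub-arms: deceased inside "excluded", unfinished surveys inside "open";
# apportioned across strata proportionally to their parent stage.
_DECEASED_BY_STRATUM = (3, 4, 9, 3, 3)          # sums to 22
_IN_PROGRESS_BY_STRATUM = (13, 15, 7, 6, 2)     # sums to 43


def reference_strata() -> pd.DataFrame:
    """Stage x stratum counts as a DataFrame (strata rows, stage columns).

    The ``net_sample`` column is the row sum of the outcome stages, per
    funnel conservation.
    """
    frame = pd.DataFrame(_STAGE_STRATUM_COUNTS, index=list(AGE_BANDS))
    frame.insert(0, "net_sample", frame.sum(axis=1))
    return frame


REFERENCE_STRATA = reference_strata()

_STUDY_START = datetime(2007, 11, 1, 8, 0)


def _record_labels():
    """(stratum, final_state) label for each of the 16,067 patients."""
    labels = []
    for i, stratum in enumerate(AGE_BANDS):
        for stage, counts in _STAGE_STRATUM_COUNTS.items():
            n = counts[i]
            if stage == "open":
                n_sip = _IN_PROGRESS_BY_STRATUM[i]
                labels += [(stratum, RecruitmentState.OPEN)] * (n - n_sip)
                labels += [(stratum, RecruitmentState.SURVEY_IN_PROGRESS)] * n_sip
            elif stage == "excluded":
                n_dec = _DECEASED_BY_STRATUM[i]
                labels += [(stratum, RecruitmentState.EXCLUDED)] * (n - n_dec)
                labels += [(stratum, RecruitmentState.DECEASED)] * n_dec
            elif stage == "refused":
                labels += [(stratum, RecruitmentState.REFUSED)] * n
            else:
                labels += [(stratum, RecruitmentState.ENROLLED)] * n
    return labels


def _event_sequence(state: RecruitmentState, base: datetime, practice_id: str,
                    study_id: str, sex: str, band: str):
    """Minimal protocol-legal event sequence ending in ``state``."""
    def ev(kind, minutes, payload=None):
        return RecruitmentEvent(
            timestamp=base + timedelta(minutes=minutes),
            practice_id=practice_id,
            study_id=study_id,
            kind=kind,
            sex=sex,
            age_band=band,
            payload=payload,
        )

    K = EventKind
    if state is RecruitmentState.OPEN:
        return [ev(K.EPR_OPEN, 0), ev(K.CLICK_OFF, 1)]
    if state is RecruitmentState.EXCLUDED:
        return [ev(K.EPR_OPEN, 0), ev(K.EXCLUDE, 1, {"reason": "other"})]
    if state is RecruitmentState.DECEASED:
        return [ev(K.EPR_OPEN, 0), ev(K.DECEASED_NOTED, 1)]
    if state is RecruitmentState.REFUSED:
        return [ev(K.EPR_OPEN, 0), ev(K.CONTACT, 1), ev(K.REFUSE, 2)]
    if state is RecruitmentState.ENROLLED:
        return [
            ev(K.EPR_OPEN, 0), ev(K.CONTACT, 1), ev(K.CONSENT, 2),
            ev(K.SURVEY_START, 3), ev(K.SURVEY_COMPLETE, 13),
        ]
    # survey started but never finished: counted as open business
    return [
        ev(K.EPR_OPEN, 0), ev(K.CONTACT, 1), ev(K.CONSENT, 2),
        ev(K.SURVEY_START, 3), ev(K.SURVEY_INTERRUPT, 8),
    ]


def reference_event_log() -> list:
    """Synthetic event log reproducing the reference study's accounting.

    Each of the 16,067 identified patients receives one minimal legal event
    sequence for their final recruitment state.  Enrolled and non-enrolled
    patients are dealt round-robin across the 25 practices so that each
    practice's identified and enrolled totals match the per-practice table;
    the within-practice demographic composition is not part of the
    published record and is arbitrary (but deterministic).

    Returns the events sorted by practice and timestamp, ready for
    :func:`ctalert.core.replay`.
    """
    labels = _record_labels()
    enrolled_pool = [lab for lab in labels if lab[1] is RecruitmentState.ENROLLED]
    other_pool = [lab for lab in labels if lab[1] is not RecruitmentState.ENROLLED]

    # Deal records to practices round-robin until each quota is filled.
    assignment = []  # (practice_id, stratum, state)
    for pool, quota_of in (
        (enrolled_pool, {p: e for p, _, e in REFERENCE_PRACTICES}),
        (other_pool, {p: n - e for p, n, e in REFERENCE_PRACTICES}),
    ):
        quotas = dict(quota_of)
        open_practices = [p for p, q in quotas.items() if q > 0]
        idx = 0
        for stratum, state in pool:
            pid = open_practices[idx % len(open_practices)]
            assignment.append((pid, stratum, state))
            quotas[pid] -= 1
            if quotas[pid] == 0:
                open_practices.remove(pid)
                if open_practices:
                    idx %= len(open_practices)
                continue
            idx += 1

    events = []
    counter = {p: 0 for p, _, _ in REFERENCE_PRACTICES}
    for pid, stratum, state in assignment:
        i = counter[pid]
        counter[pid] += 1
        base = _STUDY_START + timedelta(days=i % 350, hours=(i // 350) % 9)
        study_id = f"S{pid.zfill(2)}-{i:05d}"
        sex = stratum[0]
        events.extend(_event_sequence(state, base, pid, study_id, sex, stratum))
    events.sort(key=lambda e: (e.practice_id, e.timestamp))
    return events


def reference_practice_frame() -> pd.DataFrame:
    """Per-practice net sample and enrolment as a DataFrame."""
    return pd.DataFrame(
        REFERENCE_PRACTICES, columns=["practice_id", "net_sample", "enrolled"]
    )
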