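"""JSON-Lines event-log format and declarative run configuration.

The recruitment log is one JSON object per line with a fixed schema::

    {"timestamp": "2007-11-05T09:14:00", "practice_id": "3",
     "study_id": "SABC...", "kind": "epr_open", "sex": "F",
     "age_band": "F70-79", "payload": {...}, "recorded": true}

``payload`` and ``recorded`` are optional on input (``recorded`` defaults
to true); no other keys are allowed.  Lines parse independently and
timestamps must be non-decreasing within each practice.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .bias import SuppressionPolicy
from .core import CTAError, EventKind, ProtocolError, RecruitmentEvent
from .simulate import PracticeConfig, StaffBehaviour

REQUIRED_KEYS = frozenset(
    {"timestamp", "practice_id", "study_id", "kind", "sex", "age_band"}
)
ALLOWED_KEYS = REQUIRED_KEYS | {"payload", "recorded"}


class LogParseError(CTAError, ValueError):
    """A log line is malformed; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def event_to_dict(event: RecruitmentEvent) -> dict:
    obj = {
        "timestamp": event.timestamp.isoformat(),
        "practice_id": event.practice_id,
        "study_id": event.study_id,
        "kind": event.kind.value,
        "sex": event.sex,
        "age_band": event.age_band,
    }
    if event.payload is not None:
        obj["payload"] = event.payload
    if not event.recorded:
        obj["recorded"] = False
    return obj


def write_log(events: Sequence[RecruitmentEvent], path) -> int:
    """Write events as JSON-Lines; returns the number of lines written."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for event in events:
            fh.write(json.dumps(event_to_dict(event), sort_keys=True))
            fh.write("\n")
    return len(events)


def _parse_line(lineno: int, line: str) -> RecruitmentEvent:
    try:
        obj = json.loads(line)
    except json.JSONDecodeError as exc:
        raise LogParseError(lineno, f"invalid JSON ({exc.msg})") from exc
    if not isinstance(obj, dict):
        raise LogParseError(lineno, "line is not a JSON object")
    missing = REQUIRED_KEYS - obj.keys()
    if missing:
        raise LogParseError(lineno, f"missing key(s) {sorted(missing)}")
    extra = obj.keys() - ALLOWED_KEYS
    if extra:
        raise LogParseError(lineno, f"unknown key(s) {sorted(extra)}")
    try:
        kind = EventKind(obj["kind"])
    except ValueError:
        raise LogParseError(lineno, f"unknown event kind {obj['kind']!r}") from None
    try:
        ts = datetime.fromisoformat(obj["timestamp"])
    except ValueError:
        raise LogParseError(
            lineno, f"timestamp {obj['timestamp']!r} is not ISO-8601"
        ) from None
    return RecruitmentEvent(
        timestamp=ts,
        practice_id=str(obj["practice_id"]),
        study_id=str(obj["study_id"]),
        kind=kind,
        sex=obj["sex"],
        age_band=obj["age_band"],
        payload=obj.get("payload"),
        recorded=bool(obj.get("recorded", True)),
    )


def read_log(path) -> list:
    """Read and validate a JSON-Lines event log.

    Raises :class:`LogParseError` (naming the line) for malformed lines
    and :class:`~ctalert.core.ProtocolError` if timestamps decrease within
    a practice.
    """
    path = Path(path)
    events = []
    last_ts: dict[str, datetime] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            event = _parse_line(lineno, line)
            prev = last_ts.get(event.practice_id)
            if prev is not None and event.timestamp < prev:
                raise ProtocolError(
                    f"line {lineno}: timestamp decreases within practice "
                    f"{event.practice_id}"
                )
            last_ts[event.practice_id] = event.timestamp
            events.append(event)
    return events


@dataclass
class RunConfig:
    """Declarative simulation run: practices, staff, policy, seed."""

    practices: Sequence[PracticeConfig]
    staff: StaffBehaviour = field(default_factory=StaffBehaviour)
    suppression: Optional[SuppressionPolicy] = None
    target: int = 200
    size_threshold: int = 600
    seed: int = 0

    def __post_init__(self):
        ids = [p.practice_id for p in self.practices]
        if len(ids) != len(set(ids)):
            raise ValueError("practice_ids must be unique")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        practices = []
        for spec in raw.get("practices", []):
            spec = dict(spec)
            spec["practice_id"] = str(spec["practice_id"])
            if "study_start" in spec:
                spec["study_start"] = _as_date(spec["study_start"])
            if "downtime_windows" in spec:
                spec["downtime_windows"] = tuple(
                    (_as_date(a), _as_date(b)) for a, b in spec["downtime_windows"]
                )
            practices.append(PracticeConfig(**spec))
        staff = StaffBehaviour(**raw.get("staff", {}))
        supp = raw.get("suppression")
        suppression = None
        if supp and supp.get("enabled", True):
            suppression = SuppressionPolicy(
                tolerance=float(supp.get("tolerance", 5.0)),
                min_enrolled=int(supp.get("min_enrolled", 50)),
            )
        return cls(
            practices=practices,
            staff=staff,
            suppression=suppression,
            target=int(raw.get("target", 200)),
            size_threshold=int(raw.get("size_threshold", 600)),
            seed=int(raw.get("seed", 0)),
        )

    def digest(self) -> str:
        """Short stable digest of the configuration, for run logging."""
        blob = json.dumps(
            {
                "practices": [
                    {
                        **{
                            k: (str(v) if isinstance(v, date) else v)
                            for k, v in p.__dict__.items()
                            if k not in ("demography", "downtime_windows")
                        },
                        "demography": dict(p.demography),
                        "downtime_windows": [
                            [str(a), str(b)] for a, b in p.downtime_windows
                        ],
                    }
                    for p in self.practices
                ],
                "staff": {
                    k: (dict(v) if isinstance(v, dict) else v)
                    for k, v in self.staff.__dict__.items()
                },
                "suppression": None
                if self.suppression is None
                else [self.suppression.tolerance, self.suppression.min_enrolled],
                "target": self.target,
                "size_threshold": self.size_threshold,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:12]


def _as_date(value) -> date:
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))
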