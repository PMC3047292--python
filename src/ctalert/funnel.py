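"""Recruitment-funnel accounting: stage counts, per-practice enrolment
rates, target achievement, and practice-size stratification.

The funnel partitions the identified net sample by final recruitment
state::

    identified = open + excluded + contacted
    contacted  = refused + enrolled

with two informational sub-counts: surveys still in progress (inside
"open") and deceased EPRs (inside "excluded").
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
import pandas as pd

from .core import RecruitmentState, replay


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (spreadsheet-style), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FunnelCounts:
    """Stage totals for one event log; every patient counted once."""

    identified: int
    open: int          # includes surveys in progress
    excluded: int      # includes deceased
    contacted: int
    refused: int
    enrolled: int
    deceased_subcount: int = 0
    in_progress_subcount: int = 0

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.identified != self.open + self.excluded + self.contacted:
            raise ValueError(
                "funnel conservation violated: identified != open + excluded + contacted"
            )
        if self.contacted != self.refused + self.enrolled:
            raise ValueError(
                "funnel conservation violated: contacted != refused + enrolled"
            )
        if self.in_progress_subcount > self.open:
            raise ValueError("in-progress surveys cannot exceed open cases")
        if self.deceased_subcount > self.excluded:
            raise ValueError("deceased sub-count cannot exceed exclusions")


def _registry(log_or_registry) -> dict:
    if isinstance(log_or_registry, dict):
        return log_or_registry
    return replay(log_or_registry)


def funnel_counts(log) -> FunnelCounts:
    """Count each identified study id once, by final recruitment state.

    ``log`` is either an event list (replayed first; an illegal log raises
    :class:`~ctalert.core.ProtocolError`) or an already-replayed registry.
    Unfinished surveys count as open; deceased EPRs count inside the
    exclusion arm, each with its own sub-count.
    """
    registry = _registry(log)
    tally = {state: 0 for state in RecruitmentState}
    for record in registry.values():
        tally[record.state] += 1
    S = RecruitmentState
    return FunnelCounts(
        identified=len(registry),
        open=tally[S.OPEN] + tally[S.SURVEY_IN_PROGRESS],
        excluded=tally[S.EXCLUDED] + tally[S.DECEASED],
        contacted=tally[S.REFUSED] + tally[S.ENROLLED],
        refused=tally[S.REFUSED],
        enrolled=tally[S.ENROLLED],
        deceased_subcount=tally[S.DECEASED],
        in_progress_subcount=tally[S.SURVEY_IN_PROGRESS],
    )


def reviewed_count(counts: FunnelCounts) -> int:
    """Cases in which the staff acted on the alert: exclusions + contacts."""
    return counts.excluded + counts.contacted


def practice_table(
    log,
    target: int = 200,
    size_threshold: int = 600,
) -> pd.DataFrame:
    """Per-practice enrolment rates and target achievement.

    One row per practice with the identified net sample, enrolment count,
    enrolment percentage (of the net sample) and target achievement
    (enrolment as a percentage of the fixed per-practice goal), both
    rounded half-up to one decimal.  ``size_class`` is ``small`` for
    practices identifying fewer than ``size_threshold`` EPRs.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    registry = _registry(log)
    rows: dict[str, dict] = {}
    for record in registry.values():
        row = rows.setdefault(
            record.practice_id, {"net_sample": 0, "enrolled": 0}
        )
        row["net_sample"] += 1
        if record.state is RecruitmentState.ENROLLED:
            row["enrolled"] += 1
    table = pd.DataFrame(
        [
            {
                "practice_id": pid,
                "net_sample": row["net_sample"],
                "enrolled": row["enrolled"],
                "enrolment_pct": round_half_up(
                    100.0 * row["enrolled"] / row["net_sample"], 1
                ),
                "target_achievement_pct": round_half_up(
                    100.0 * row["enrolled"] / target, 1
                ),
                "size_class": "small" if row["net_sample"] < size_threshold else "large",
            }
            for pid, row in rows.items()
        ]
    )
    return table.sort_values(
        "practice_id", key=lambda s: s.map(lambda x: (len(x), x))
    ).reset_index(drop=True)


def size_strata_summary(
    rows: pd.DataFrame,
    threshold: int = 600,
    poor_cutoff: float = 5.0,
) -> pd.DataFrame:
    """Pooled recruitment by practice size class.

    Partitions the per-practice table at ``threshold`` identified EPRs and
    reports, per stratum: number of practices, summed net sample, summed
    enrolment, the pooled enrolment percentage (rounded half-up to an
    integer, as quoted in prose), and the number of poor recruiters
    (enrolment below ``poor_cutoff`` percent of their own net sample).
    """
    if rows.empty:
        raise ValueError("practice table is empty")
    out = []
    for name, mask in (
        ("small", rows["net_sample"] < threshold),
        ("large", rows["net_sample"] >= threshold),
    ):
        part = rows[mask]
        net = int(part["net_sample"].sum())
        enr = int(part["enrolled"].sum())
        out.append(
            {
                "size_class": name,
                "n_practices": int(len(part)),
                "net_sample": net,
                "enrolled": enr,
                "pooled_pct": int(round_half_up(100.0 * enr / net)) if net else 0,
                "poor_recruiters": int((part["enrolment_pct"] < poor_cutoff).sum()),
            }
        )
    return pd.DataFrame(out).set_index("size_class")


def overall_rates(counts: FunnelCounts, target: int = 200, n_practices: int = 25) -> dict:
    """Study-wide summary percentages (rounded half-up to one decimal).

    * ``enrolment_pct`` — enrolled as a share of the identified net sample;
    * ``target_achievement_pct`` — enrolled as a share of the total goal
      (``target`` x ``n_practices``);
    * ``reviewed_pct`` — alert responses (exclusions + contacts) per
      identified EPR;
    * ``contact_to_enrolment_pct`` — enrolled per contacted patient;
    * ``survey_completion_pct`` — completed surveys per started survey.
    """
    started = counts.enrolled + counts.in_progress_subcount
    return {
        "enrolment_pct": round_half_up(100.0 * counts.enrolled / counts.identified, 1),
        "target_achievement_pct": round_half_up(
            100.0 * counts.enrolled / (target * n_practices), 1
        ),
        "reviewed_pct": round_half_up(
            100.0 * reviewed_count(counts) / counts.identified, 1
        ),
        "contact_to_enrolment_pct": round_half_up(
            100.0 * counts.enrolled / counts.contacted, 1
        )
        if counts.contacted
        else 0.0,
        "survey_completion_pct": round_half_up(
            100.0 * counts.enrolled / started, 1
        )
        if started
        else 0.0,
    }


def consort_text(counts: FunnelCounts) -> str:
    """CONSORT-style flow block for one log, as plain text."""
    lines = [
        f"identified (net sample)        {counts.identified:>7,}",
        f"|- open / no response          {counts.open:>7,}"
        f"   (incl. {counts.in_progress_subcount} surveys in progress)",
        f"|- excluded                    {counts.excluded:>7,}"
        f"   (incl. {counts.deceased_subcount} deceased)",
        f"`- contacted                   {counts.contacted:>7,}",
        f"   |- refused                  {counts.refused:>7,}",
        f"   `- enrolled                 {counts.enrolled:>7,}",
        f"reviewed (excluded+contacted)  {reviewed_count(counts):>7,}",
    ]
    return "\n".join(lines)


def plot_funnel(counts: FunnelCounts, ax=None):
    """Horizontal bar chart of the funnel stages (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    stages = ["identified", "open", "excluded", "contacted", "refused", "enrolled"]
    values = [getattr(counts, s) for s in stages]
    ax.barh(stages[::-1], values[::-1], color="#4878a8")
    ax.set_xlabel("patients")
    ax.set_title("Recruitment funnel")
    for y, v in enumerate(values[::-1]):
        ax.text(v, y, f" {v:,}", va="center")
    return ax
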