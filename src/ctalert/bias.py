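"""Demographic selection-bias monitoring and adaptive alert suppression.

Because the alert tool registers *every* eligible patient whose chart is
opened — not only the ones the staff chooses to approach — the study centre
can compare the demography of the enrolled sample against the full net
sample in real time.  This module provides:

* :func:`stage_demography` — stage x stratum counts and column percentages
  (the selection-bias table);
* :func:`chi_square_bias_test` — Pearson chi-square contingency test of
  enrolled vs net-sample demography;
* :func:`representation_ratio` — a stratum's enrolled share over its net
  share (1 = proportional enrolment);
* :func:`registry_consistency` — completeness audit of the pseudonymised
  registry against a full panel query;
* :class:`SuppressionPolicy` / :func:`update_suppression` — adaptive
  muting of the reminder for overrepresented strata until enrolment
  re-approaches the net-sample demography.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .core import AGE_BANDS, CTAError, InvalidInputError, RecruitmentState
from .funnel import _registry, round_half_up


class DegenerateTableError(CTAError, ValueError):
    """A contingency table has a zero expected cell."""


class UndefinedRatioError(CTAError, ZeroDivisionError):
    """Representation ratio requested for a stratum with zero net share."""


STAGES = ("net_sample", "open", "excluded", "refused", "enrolled")

_STATE_STAGE = {
    RecruitmentState.OPEN: "open",
    RecruitmentState.SURVEY_IN_PROGRESS: "open",
    RecruitmentState.EXCLUDED: "excluded",
    RecruitmentState.DECEASED: "excluded",
    RecruitmentState.REFUSED: "refused",
    RecruitmentState.ENROLLED: "enrolled",
}


@dataclass(frozen=True)
class StrataTable:
    """Stage x demographic-stratum counts for one log.

    ``counts`` is a DataFrame with the five strata as rows and the stages
    (net_sample, open, excluded, refused, enrolled) as columns; the
    net-sample column equals the row-wise sum of the outcome stages.
    """

    counts: pd.DataFrame

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "StrataTable":
        frame = counts.copy()
        if "net_sample" not in frame.columns:
            frame.insert(0, "net_sample", frame.sum(axis=1))
        outcome = [c for c in frame.columns if c != "net_sample"]
        if not (frame["net_sample"] == frame[outcome].sum(axis=1)).all():
            raise ValueError("net_sample column must equal the sum of the outcome stages")
        return cls(frame)

    def stage_total(self, stage: str) -> int:
        return int(self.counts[stage].sum())

    def share(self, stage: str, stratum: str) -> float:
        """Unrounded share of ``stratum`` within ``stage``."""
        total = self.stage_total(stage)
        if total == 0:
            return float("nan")
        return float(self.counts.at[stratum, stage]) / total

    def shares(self, stage: str) -> pd.Series:
        total = self.stage_total(stage)
        return self.counts[stage] / total if total else self.counts[stage] * np.nan

    def sex_counts(self, stage: str) -> pd.Series:
        """Counts aggregated to sex ('F', 'M') within a stage."""
        sex = self.counts.index.str[0]
        return self.counts.groupby(sex)[stage].sum()

    def percent_frame(self) -> pd.DataFrame:
        """Column percentages rounded half-up to one decimal, for reporting."""
        out = {}
        for stage in self.counts.columns:
            total = self.stage_total(stage)
            out[stage] = [
                round_half_up(100.0 * c / total, 1) if total else 0.0
                for c in self.counts[stage]
            ]
        return pd.DataFrame(out, index=self.counts.index)

    def within_sex_percent(self, sex: str) -> pd.DataFrame:
        """Age-band percentages within one sex (the published table layout)."""
        part = self.counts[self.counts.index.str.startswith(sex)]
        out = {}
        for stage in part.columns:
            total = part[stage].sum()
            out[stage] = [
                round_half_up(100.0 * c / total, 1) if total else 0.0
                for c in part[stage]
            ]
        return pd.DataFrame(out, index=part.index)


def stage_demography(log) -> StrataTable:
    """Tabulate final recruitment states by demographic stratum.

    Surveys in progress count as open and deceased EPRs count in the
    exclusion arm, mirroring the funnel accounting.
    """
    registry = _registry(log)
    counts = pd.DataFrame(
        0, index=list(AGE_BANDS), columns=list(STAGES[1:]), dtype=int
    )
    for record in registry.values():
        counts.at[record.age_band, _STATE_STAGE[record.state]] += 1
    return StrataTable.from_counts(counts)


@dataclass(frozen=True)
class BiasTestResult:
    """Pearson chi-square test of demographic selection bias."""

    statistic: float
    df: int
    p_value: float
    table_used: np.ndarray

    def __str__(self) -> str:
        return (
            f"chi2 = {self.statistic:.3f}, df = {self.df}, p = {self.p_value:.4g}"
        )


def chi_square_bias_test(
    net_counts: Sequence[int],
    enrolled_counts: Sequence[int],
    mode: str = "enrolled_vs_rest",
) -> BiasTestResult:
    """Pearson chi-square test of enrolled vs net-sample demography.

    In the default ``enrolled_vs_rest`` mode the 2 x k table compares
    enrolees against the net-sample *non*-enrolees, so the two groups are
    disjoint and the independence test is exact in its assumptions.  The
    ``enrolled_vs_net`` mode compares enrolees against the full net sample
    (overlapping groups) and is kept for reproducing analyses framed that
    way; its p-values are conservative.

    No continuity correction is applied; df = k - 1 for k strata.
    """
    net = np.asarray(net_counts, dtype=float)
    enrolled = np.asarray(enrolled_counts, dtype=float)
    if net.shape != enrolled.shape or net.ndim != 1:
        raise InvalidInputError("net and enrolled counts must be 1-D and congruent")
    if (net < 0).any() or (enrolled < 0).any():
        raise InvalidInputError("counts must be non-negative")
    if mode == "enrolled_vs_rest":
        if (enrolled > net).any():
            raise InvalidInputError(
                "enrolled counts cannot exceed net counts per stratum"
            )
        table = np.vstack([enrolled, net - enrolled])
    elif mode == "enrolled_vs_net":
        table = np.vstack([enrolled, net])
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        raise DegenerateTableError("contingency table has a zero expected cell")
    statistic, p_value, df, _ = stats.chi2_contingency(table, correction=False)
    return BiasTestResult(
        statistic=float(statistic), df=int(df), p_value=float(p_value),
        table_used=table,
    )


def representation_ratio(stratum: str, table: StrataTable) -> float:
    """Enrolled share of a stratum divided by its net-sample share.

    Uses unrounded shares; 1.0 means proportional enrolment, below 1 the
    stratum is underrepresented among enrolees.  Scale-invariant in the
    counts.
    """
    net_share = table.share("net_sample", stratum)
    if not net_share > 0:
        raise UndefinedRatioError(
            f"stratum {stratum!r} has zero net-sample share"
        )
    return table.share("enrolled", stratum) / net_share


def sex_representation_ratio(sex: str, table: StrataTable) -> float:
    """Representation ratio for one sex, aggregating its age bands."""
    net = table.sex_counts("net_sample")
    enr = table.sex_counts("enrolled")
    net_share = net[sex] / net.sum()
    if not net_share > 0:
        raise UndefinedRatioError(f"sex {sex!r} has zero net-sample share")
    return float((enr[sex] / enr.sum()) / net_share)


def registry_consistency(registry_ids: Set[str], oracle_ids: Set[str]) -> float:
    """Registry completeness: |registry ∩ oracle| / |oracle|.

    The oracle is a full database query of the practice software for
    eligible patients seen in the study window; the registry is what the
    alert tool captured.  Software downtime lowers the overlap.
    """
    oracle_ids = set(oracle_ids)
    if not oracle_ids:
        raise InvalidInputError("oracle id set must be non-empty")
    return len(set(registry_ids) & oracle_ids) / len(oracle_ids)


@dataclass(frozen=True)
class SuppressionPolicy:
    """Adaptive reminder suppression for overrepresented strata.

    A stratum is muted while its enrolled share exceeds its net-sample
    share by more than ``tolerance`` percentage points; it is released as
    soon as the excess falls back within tolerance.  Nothing is suppressed
    before ``min_enrolled`` enrolments, so early noise cannot mute anyone.
    """

    tolerance: float = 5.0       # percentage points
    min_enrolled: int = 50
    suppressed_strata: frozenset = frozenset()

    def __post_init__(self):
        if self.tolerance < 0:
            raise InvalidInputError("tolerance must be non-negative")
        unknown = set(self.suppressed_strata) - set(AGE_BANDS)
        if unknown:
            raise InvalidInputError(f"unknown strata in policy: {sorted(unknown)}")


def update_suppression(
    policy: SuppressionPolicy, table: StrataTable
) -> SuppressionPolicy:
    """Recompute the suppressed-strata set from current enrolment shares."""
    total_enrolled = table.stage_total("enrolled")
    if total_enrolled < policy.min_enrolled:
        return replace(policy, suppressed_strata=frozenset())
    excess = 100.0 * (table.shares("enrolled") - table.shares("net_sample"))
    suppressed = frozenset(excess.index[excess > policy.tolerance])
    return replace(policy, suppressed_strata=suppressed)


def total_variation(p: Sequence[float], q: Sequence[float]) -> float:
    """Total-variation distance between two discrete distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return 0.5 * float(np.abs(p / p.sum() - q / q.sum()).sum())


def bias_report(table: StrataTable, policy: Optional[SuppressionPolicy] = None) -> str:
    """Structured-text bias report: tests, ratios, active suppressions."""
    lines = ["Selection-bias report", "=" * 21, ""]
    sex_net = table.sex_counts("net_sample")
    sex_enr = table.sex_counts("enrolled")
    test = chi_square_bias_test(
        sex_net.to_numpy(), sex_enr.to_numpy(), mode="enrolled_vs_rest"
    )
    lines.append(f"sex (enrolled vs rest of net sample): {test}")
    for sex in ("F", "M"):
        strata = [b for b in AGE_BANDS if b.startswith(sex)]
        sub = table.counts.loc[strata]
        test = chi_square_bias_test(
            sub["net_sample"].to_numpy(), sub["enrolled"].to_numpy()
        )
        label = "women" if sex == "F" else "men"
        lines.append(f"age within {label}: {test}")
    lines.append("")
    lines.append("representation ratios (enrolled share / net share):")
    for sex, label in (("F", "women"), ("M", "men")):
        lines.append(f"  {label:<8} {sex_representation_ratio(sex, table):.3f}")
    for band in AGE_BANDS:
        lines.append(f"  {band:<8} {representation_ratio(band, table):.3f}")
    if policy is not None:
        active = sorted(policy.suppressed_strata) or ["none"]
        lines.append("")
        lines.append(
            f"suppression (tolerance {policy.tolerance:g} pp, "
            f"min {policy.min_enrolled} enrolled): {', '.join(active)}"
        )
    return "\n".join(lines)
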