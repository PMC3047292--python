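"""Selection-bias quantification, chi-square testing, registry audit,
and adaptive suppression."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctalert as ct
from ctalert.bias import (
    DegenerateTableError,
    StrataTable,
    UndefinedRatioError,
    chi_square_bias_test,
)
from ctalert.core import AGE_BANDS, replay


def pearson_oracle(table):
    """Textbook Pearson chi-square, written independently: sum over cells
    of (observed - expected)^2 / expected with products of margins."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    return stat


def table_from_counts(net, enrolled):
    counts = pd.DataFrame(
        {"enrolled": enrolled, "open": [n - e for n, e in zip(net, enrolled)]},
        index=list(AGE_BANDS)[: len(net)],
    )
    return StrataTable.from_counts(counts)


class TestStageDemography:
    def test_reference_sex_shares(self, reference_registry):
        """Women are 72.0% of the net sample but 81.3% of enrolees."""
        table = ct.stage_demography(reference_registry)
        sex_pct = {
            stage: 100 * table.sex_counts(stage)["F"] / table.sex_counts(stage).sum()
            for stage in ("net_sample", "open", "excluded", "refused", "enrolled")
        }
        assert round(sex_pct["net_sample"], 1) == 72.0
        assert round(sex_pct["open"], 1) == 70.5
        assert round(sex_pct["excluded"], 1) == 73.2
        assert round(sex_pct["refused"], 1) == 69.0
        assert round(sex_pct["enrolled"], 1) == 81.3

    def test_reference_within_sex_age_shares(self, reference_registry):
        """Within-sex age-band column percentages of the reference study."""
        table = ct.stage_demography(reference_registry)
        women = table.within_sex_percent("F")
        assert list(women["net_sample"]) == [29.2, 32.4, 38.4]
        assert list(women["excluded"]) == [16.4, 25.7, 57.9]
        assert list(women["refused"]) == [32.6, 37.1, 30.3]
        assert list(women["enrolled"]) == [37.6, 41.9, 20.6]
        men = table.within_sex_percent("M")
        assert list(men["net_sample"]) == [56.4, 43.6]
        assert list(men["enrolled"]) == [70.6, 29.4]

    def test_single_stratum_log_is_hundred_percent(self):
        from conftest import events_for_state
        from ctalert.core import RecruitmentState

        table = ct.stage_demography(
            events_for_state("a", RecruitmentState.ENROLLED, band="M80+", sex="M")
        )
        assert table.percent_frame().loc["M80+", "enrolled"] == 100.0

    def test_stage_columns_sum_to_hundred(self, reference_registry):
        pct = ct.stage_demography(reference_registry).percent_frame()
        assert ((pct.sum() - 100).abs() <= 0.2).all()


class TestChiSquare:
    def test_reference_sex_table_matches_hand_coded_pearson(self):
        """2x2 enrolees vs net-sample non-enrolees, sexes as columns."""
        result = chi_square_bias_test([11574, 4493], [1240, 286])
        expected = pearson_oracle([[1240, 286], [11574 - 1240, 4493 - 286]])
        assert result.statistic == pytest.approx(expected, abs=1e-9)
        assert result.df == 1
        assert result.p_value < 1e-6  # the sex bias is unambiguous

    @given(
        st.lists(
            st.tuples(st.integers(11, 5000), st.integers(1, 10)),
            min_size=2,
            max_size=5,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_oracle_on_random_tables(self, cells):
        net = [n for n, _ in cells]
        enrolled = [e for _, e in cells]
        result = chi_square_bias_test(net, enrolled)
        oracle = pearson_oracle(
            [enrolled, [n - e for n, e in zip(net, enrolled)]]
        )
        assert result.statistic == pytest.approx(oracle, abs=1e-9)

    def test_identical_proportions_give_zero_statistic(self):
        result = chi_square_bias_test([1000, 3000], [100, 300])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_degrees_of_freedom_for_three_strata(self):
        result = chi_square_bias_test([300, 300, 300], [30, 40, 50])
        assert result.df == 2

    def test_overlapping_mode_uses_full_net_sample(self):
        result = chi_square_bias_test([100, 100], [50, 10], mode="enrolled_vs_net")
        assert (result.table_used[1] == [100, 100]).all()

    def test_zero_expected_cell_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square_bias_test([100, 0], [10, 0])

    def test_enrolled_exceeding_net_rejected(self):
        with pytest.raises(ct.InvalidInputError):
            chi_square_bias_test([100, 100], [150, 10])


class TestRepresentationRatio:
    def test_men_overall_ratio(self, reference_registry):
        """Men: 28% of the net sample, 18.7% of enrolees -> ratio 0.670."""
        table = ct.stage_demography(reference_registry)
        assert ct.sex_representation_ratio("M", table) == pytest.approx(
            (286 / 1526) / (4493 / 16067), abs=1e-12
        )
        assert round(ct.sex_representation_ratio("M", table), 3) == 0.670

    def test_oldest_women_underrepresented(self, reference_registry):
        """Women 80+ hold 38.4% of the women's net sample but 20.6% of the
        women enrolees: within-sex representation ratio ~ 0.536."""
        table = ct.stage_demography(reference_registry)
        women = table.counts[table.counts.index.str.startswith("F")]
        ratio = (women.at["F80+", "enrolled"] / women["enrolled"].sum()) / (
            women.at["F80+", "net_sample"] / women["net_sample"].sum()
        )
        assert ratio == pytest.approx(20.6 / 38.4, abs=5e-3)

    def test_proportional_sample_is_unity(self):
        table = table_from_counts([100, 200], [10, 20])
        assert ct.representation_ratio("F60-69", table) == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = table_from_counts([100, 200, 300], [10, 15, 30])
        b = table_from_counts([700, 1400, 2100], [70, 105, 210])
        for band in a.counts.index:
            assert ct.representation_ratio(band, a) == pytest.approx(
                ct.representation_ratio(band, b)
            )

    def test_zero_net_share_is_undefined(self):
        table = table_from_counts([100, 0], [10, 0])
        with pytest.raises(UndefinedRatioError):
            ct.representation_ratio("F70-79", table)


class TestRegistryConsistency:
    def test_identical_sets(self):
        assert ct.registry_consistency({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert ct.registry_consistency({"a"}, {"b", "c"}) == 0.0

    def test_empty_oracle_rejected(self):
        with pytest.raises(ct.InvalidInputError):
            ct.registry_consistency({"a"}, set())

    def test_downtime_lowers_overlap_to_analytic_expectation(self):
        """Patients seen only during downtime never reach the registry.
        With Poisson(lambda) visits uniform in time and a downtime window
        covering fraction f of the study, the expected overlap is
        1 - (exp(-lambda(1-f)) - exp(-lambda)) / (1 - exp(-lambda))."""
        from datetime import date

        lam, f = 1.0, 107 / 366
        expected = 1 - (math.exp(-lam * (1 - f)) - math.exp(-lam)) / (
            1 - math.exp(-lam)
        )
        overlaps = []
        n_oracle = 0
        for seed in range(20):
            cfg = ct.PracticeConfig(
                practice_id="dt",
                panel_size=400,
                visit_rate=lam / 12,
                downtime_windows=((date(2008, 1, 1), date(2008, 4, 17)),),
            )
            res = ct.simulate_practice(cfg, ct.StaffBehaviour(), seed=seed)
            overlaps.append(ct.registry_consistency(res.registry_ids, res.oracle_ids))
            n_oracle += len(res.oracle_ids)
        se = math.sqrt(expected * (1 - expected) / n_oracle)
        assert abs(np.mean(overlaps) - expected) < 3 * se


class TestSuppression:
    def test_equal_shares_suppress_nothing(self):
        table = table_from_counts([1000, 1000], [100, 100])
        policy = ct.update_suppression(ct.SuppressionPolicy(), table)
        assert policy.suppressed_strata == frozenset()

    def test_below_min_enrolled_suppresses_nothing(self):
        table = table_from_counts([1000, 1000], [30, 2])
        policy = ct.update_suppression(ct.SuppressionPolicy(min_enrolled=50), table)
        assert policy.suppressed_strata == frozenset()

    def test_overrepresented_young_women_suppressed(self, reference_registry):
        """In the reference study women 60-69 are 21.0% of the net sample
        but 30.5% of enrolees: a 5-point tolerance mutes the stratum."""
        table = ct.stage_demography(reference_registry)
        policy = ct.update_suppression(ct.SuppressionPolicy(tolerance=5.0), table)
        assert "F60-69" in policy.suppressed_strata
        assert "F80+" not in policy.suppressed_strata

    def test_release_when_excess_falls(self):
        high = table_from_counts([1000, 1000], [180, 60])
        policy = ct.update_suppression(ct.SuppressionPolicy(tolerance=5.0), high)
        assert "F60-69" in policy.suppressed_strata
        balanced = table_from_counts([1000, 1000], [130, 110])
        policy = ct.update_suppression(policy, balanced)
        assert policy.suppressed_strata == frozenset()

    def test_unknown_stratum_rejected(self):
        with pytest.raises(ct.InvalidInputError):
            ct.SuppressionPolicy(suppressed_strata=frozenset({"F50-59"}))

    def test_bias_report_mentions_tests_and_ratios(self, reference_registry):
        table = ct.stage_demography(reference_registry)
        text = ct.bias_report(table, ct.SuppressionPolicy())
        assert "chi2" in text and "representation ratios" in text
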