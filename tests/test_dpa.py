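import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pvmlsd import (
    ContingencyTable,
    ICResult,
    InestimableError,
    ReportSet,
    RORResult,
    adjusted_ror,
    crude_ror,
    dpa_signal,
    ic025_approx,
    information_component,
)

from conftest import make_report

cells = st.integers(min_value=1, max_value=500)


class TestCrudeROR:
    def test_textbook_table(self):
        res = crude_ror(ContingencyTable(10, 20, 5, 40))
        assert res.estimate == pytest.approx(4.0)
        assert not res.corrected

    @pytest.mark.parametrize("k", [1, 7, 100])
    def test_symmetric_table_is_null(self, k):
        res = crude_ror(ContingencyTable(k, k, k, k))
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_cell_triggers_correction_hand_arithmetic(self):
        res = crude_ror(ContingencyTable(3, 0, 1, 5))
        a, b, c, d = 3.5, 0.5, 1.5, 5.5
        expect = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert res.corrected
        assert res.estimate == pytest.approx(expect)
        assert res.ci_low == pytest.approx(expect * math.exp(-1.96 * se))
        assert res.ci_high == pytest.approx(expect * math.exp(1.96 * se))

    @settings(derandomize=True, max_examples=100)
    @given(cells, cells, cells, cells)
    def test_column_swap_inverts_odds_ratio(self, a, b, c, d):
        r1 = crude_ror(ContingencyTable(a, b, c, d))
        r2 = crude_ror(ContingencyTable(b, a, d, c))
        assert r1.estimate * r2.estimate == pytest.approx(1.0)

    def test_interval_ordering_enforced(self):
        with pytest.raises(Exception):
            RORResult(estimate=1.0, ci_low=2.0, ci_high=3.0)


class TestInformationComponent:
    def test_observed_equal_expected_gives_zero(self):
        # (4,4,4,4): E = 8*8/16 = 4 = a, so IC = log2(4.5/4.5) = 0
        res = information_component(ContingencyTable(4, 4, 4, 4))
        assert res.expected == pytest.approx(4.0)
        assert res.ic == pytest.approx(0.0)

    def test_strictly_increasing_in_a(self):
        ics = [
            information_component(ContingencyTable(a, 80, 50, 850)).ic for a in range(1, 60, 5)
        ]
        assert all(x < y for x, y in zip(ics, ics[1:]))

    @settings(derandomize=True, max_examples=100)
    @given(cells, cells, cells, cells)
    def test_credible_bounds_bracket_point_estimate(self, a, b, c, d):
        res = information_component(ContingencyTable(a, b, c, d))
        assert res.ic025 <= res.ic <= res.ic975

    def test_gamma_quantile_matches_monte_carlo(self):
        """IC025 against the empirical 2.5% quantile of 10^6 gamma
        posterior draws (independent route to the same posterior)."""
        table = ContingencyTable(20, 80, 50, 850)
        res = information_component(table)
        rng = np.random.default_rng(12345)
        shape, rate = table.a + 0.5, res.expected + 0.5
        draws = np.log2(rng.gamma(shape, 1.0 / rate, size=1_000_000))
        assert res.ic025 == pytest.approx(np.quantile(draws, 0.025), abs=0.01)
        assert res.ic975 == pytest.approx(np.quantile(draws, 0.975), abs=0.01)

    @pytest.mark.parametrize("table", [
        ContingencyTable(5, 20, 10, 200),
        ContingencyTable(20, 80, 50, 850),
        ContingencyTable(120, 400, 90, 2000),
    ])
    def test_closed_form_approximation_cross_check(self, table):
        res = information_component(table)
        assert ic025_approx(table) == pytest.approx(res.ic025, abs=0.05)

    def test_empty_margin_is_degenerate(self):
        from pvmlsd import DegenerateDataError

        with pytest.raises(DegenerateDataError):
            information_component(ContingencyTable(0, 0, 3, 5))


def reports_for_table(a, b, c, d):
    """Report-level data realizing a 2×2 table exactly."""
    reports, i = [], 0
    for n, drugs, aes in (
        (a, ["DRUG"], ["P1"]),
        (b, ["DRUG"], ["P2"]),
        (c, ["COMP1"], ["P1"]),
        (d, ["COMP1"], ["P2"]),
    ):
        for _ in range(n):
            reports.append(make_report(f"r{i}", drugs, aes))
            i += 1
    return ReportSet(reports)


class TestAdjustedROR:
    def test_no_covariates_recovers_sample_odds_ratio(self):
        rs = reports_for_table(10, 20, 5, 40)
        adj = adjusted_ror(rs, "DRUG", "P1", {"COMP1"}, covariates=())
        crude = crude_ror(ContingencyTable(10, 20, 5, 40))
        assert adj.estimate == pytest.approx(crude.estimate, rel=1e-6)
        assert adj.adjusted

    def test_independent_covariate_leaves_estimate_near_crude(self):
        # covariate drawn independently of exposure and outcome
        rng = np.random.default_rng(7)
        reports = []
        for i in range(600):
            exposed = rng.random() < 0.5
            has_ae = rng.random() < (0.30 if exposed else 0.10)
            reports.append(
                make_report(
                    f"r{i}",
                    ["DRUG"] if exposed else ["COMP1"],
                    ["P1"] if has_ae else ["P2"],
                    sex=str(rng.choice(["male", "female"])),
                )
            )
        rs = ReportSet(reports)
        crude = adjusted_ror(rs, "DRUG", "P1", {"COMP1"}, covariates=())
        adj = adjusted_ror(rs, "DRUG", "P1", {"COMP1"}, covariates=("sex",))
        assert adj.estimate == pytest.approx(crude.estimate, rel=0.05)

    def test_constant_outcome_is_inestimable(self):
        rs = ReportSet(
            [make_report("a", ["DRUG"], ["P1"]), make_report("b", ["COMP1"], ["P1"])]
        )
        with pytest.raises(InestimableError):
            adjusted_ror(rs, "DRUG", "P1", {"COMP1"})

    def test_empty_exposure_arm_is_inestimable(self):
        rs = ReportSet([make_report("a", ["DRUG"], ["P1"]), make_report("b", ["DRUG"], ["P2"])])
        with pytest.raises(InestimableError):
            adjusted_ror(rs, "DRUG", "P1", {"COMP1"})


class TestSignalCriteria:
    def test_ror_lower_bound_exactly_one_is_a_signal(self):
        res = RORResult(estimate=2.0, ci_low=1.0, ci_high=4.0)
        assert dpa_signal(res) is True

    def test_ic025_exactly_zero_is_not_a_signal(self):
        res = ICResult(observed=10, expected=5.0, ic=0.5, ic025=0.0, ic975=1.0)
        assert dpa_signal(res) is False

    def test_positive_ic025_is_a_signal(self):
        res = ICResult(observed=10, expected=5.0, ic=0.5, ic025=0.3, ic975=1.0)
        assert dpa_signal(res) is True

    def test_gamma_quantile_sanity_against_scipy_interval(self):
        table = ContingencyTable(20, 80, 50, 850)
        res = information_component(table)
        lo, hi = stats.gamma.interval(0.95, table.a + 0.5, scale=1 / (res.expected + 0.5))
        assert res.ic025 == pytest.approx(math.log2(lo))
        assert res.ic975 == pytest.approx(math.log2(hi))
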