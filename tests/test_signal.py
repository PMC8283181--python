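"""Disproportionality statistics: closed forms, criteria, table layout."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from faerspv.signal import (ComparisonDesign, ContingencyTable,
                            DisproportionalityModel, Selector, SignalStats,
                            build_contingency, classify_signal, compute_ic,
                            compute_ror, default_designs, expected_count,
                            run_signal_table)

cells = st.integers(min_value=0, max_value=100_000)


class TestRor:
    def test_point_estimate_examples(self):
        ror, _, _, corrected = compute_ror(ContingencyTable(10, 90, 100, 9000))
        assert ror == pytest.approx(10.0) and not corrected
        ror, lo, hi, _ = compute_ror(ContingencyTable(5, 5, 5, 5))
        assert ror == pytest.approx(1.0) and lo < 1 < hi

    def test_ci_against_independent_reference(self):
        # statsmodels' 2x2 table machinery as the independent oracle
        from scipy.stats import norm
        from statsmodels.stats.contingency_tables import Table2x2

        rng = np.random.default_rng(1234)
        z = float(norm.ppf(0.975))
        for _ in range(200):
            a, b, c, d = rng.integers(1, 2000, size=4)
            table = ContingencyTable(int(a), int(b), int(c), int(d))
            ror, lo, hi, corrected = compute_ror(table, z=z)
            assert not corrected
            ref = Table2x2([[a, b], [c, d]])
            assert ror == pytest.approx(ref.oddsratio, rel=1e-10)
            ref_lo, ref_hi = ref.oddsratio_confint(alpha=0.05)
            assert lo == pytest.approx(ref_lo, rel=1e-8)
            assert hi == pytest.approx(ref_hi, rel=1e-8)

    def test_specific_ci_to_six_significant_digits(self):
        # frozen from the closed form exp(ln ROR +/- 1.959964*sqrt(sum 1/cell))
        ror, lo, hi, _ = compute_ror(ContingencyTable(3, 97, 300, 99700))
        assert ror == pytest.approx(10.2783505, rel=1e-6)
        assert lo == pytest.approx(3.239804, rel=1e-6)
        assert hi == pytest.approx(32.60829, rel=1e-6)

    @given(cells, cells, cells, cells)
    def test_brute_force_identity_on_positive_tables(self, a, b, c, d):
        table = ContingencyTable(a + 1, b + 1, c + 1, d + 1)
        ror, lo, hi, corrected = compute_ror(table)
        assert not corrected
        assert ror == pytest.approx(
            (table.a * table.d) / (table.b * table.c), rel=1e-12)
        assert lo <= ror <= hi

    def test_zero_cell_haldane_anscombe(self):
        ror, lo, hi, corrected = compute_ror(ContingencyTable(0, 10, 10, 100))
        assert corrected
        assert ror == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))
        assert lo <= ror <= hi


class TestExpectedCount:
    def test_arithmetic(self):
        assert expected_count(1000, 200, 100_000) == pytest.approx(2.0)
        assert expected_count(0, 123, 1000) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            expected_count(1, 1, 0)

    @given(cells, cells, cells, cells)
    def test_margin_identity_on_random_tables(self, a, b, c, d):
        table = ContingencyTable(a, b + 1, c, d + 1)
        exp = expected_count(table.n_drug, table.n_event, table.n_total)
        assert exp == pytest.approx(
            (table.a + table.b) * (table.a + table.c) / table.n_total)


class TestIc:
    def test_power_of_two_case(self):
        ic, _ = compute_ic(15, 7.25)   # (15.5 / 7.75) = 2 exactly
        assert ic == 1.0

    def test_identity_case(self):
        for n in (0, 1, 7, 705):
            assert compute_ic(n, n)[0] == 0.0

    def test_lower_bound_formula(self):
        ic, ic025 = compute_ic(705, 150.0)
        assert ic025 == pytest.approx(
            ic - 3.3 * 705.5 ** -0.5 - 2 * 705.5 ** -1.5, abs=1e-12)

    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0, max_value=1e6, allow_nan=False))
    def test_lower_bound_below_point_estimate(self, n_obs, n_exp):
        ic, ic025 = compute_ic(n_obs, n_exp)
        assert ic025 < ic

    @given(st.floats(min_value=0.01, max_value=1e5, allow_nan=False))
    def test_strictly_increasing_in_observed(self, n_exp):
        ics = [compute_ic(n, n_exp)[0] for n in range(0, 50, 7)]
        assert all(x < y for x, y in zip(ics, ics[1:]))

    def test_decreasing_in_expected(self):
        ics = [compute_ic(20, e)[0] for e in (1, 5, 20, 100)]
        assert all(x > y for x, y in zip(ics, ics[1:]))


class TestSignalCriteria:
    @pytest.mark.parametrize("n, ror025, ic025, want_ror, want_ic", [
        (705, 4.51, 2.11, True, True),     # clear class-level signal
        (22, 0.84, -0.31, False, False),   # interval spans the null
        (2, 5.0, 1.0, False, True),        # below the 3-case minimum
        (3, 5.0, 1.0, True, True),         # exactly at the minimum
        (100, 1.0, 0.0, False, False),     # bounds must strictly exceed
        (100, 1.0001, 0.0001, True, True),
    ])
    def test_truth_table(self, n, ror025, ic025, want_ror, want_ic):
        stats = SignalStats(n_observed=n, ror=ror025 * 1.2, ror025=ror025,
                            ror975=ror025 * 2, ic=ic025 + 0.2, ic025=ic025)
        out = classify_signal(stats)
        assert out.signal_ror is want_ror
        assert out.signal_ic is want_ic

    def test_custom_minimum_case_rule(self):
        stats = SignalStats(n_observed=4, ror025=2.0)
        assert classify_signal(stats, n_min=5).signal_ror is False


class TestContingency:
    def test_exhaustive_enumeration(self):
        from faerspv.io import SafetyReport
        from faerspv.io import DrugUse

        def rep(i, drug, event):
            drugs = [DrugUse(raw_name=drug, active_ingredient=drug, role="PS",
                             seq="1", name=drug)] if drug else []
            return SafetyReport(
                case_id=str(i), primary_id=str(i), case_version=1,
                receipt_date=None, event_date=None, age_years=None, sex=None,
                region=None, reporter=None, drugs=drugs,
                reactions={"pericardial effusion"} if event else {"nausea"},
                outcomes=set(), indications=set())

        reports = (
            [rep(i, "nivolumab", True) for i in range(2)]
            + [rep(i + 10, "nivolumab", False) for i in range(3)]
            + [rep(20, None, True)]
            + [rep(i + 30, None, False) for i in range(4)]
        )
        design = ComparisonDesign("nivo", Selector("label", "nivolumab"))
        table = build_contingency(reports, design)
        assert (table.a, table.b, table.c, table.d) == (2, 3, 1, 4)

    def test_named_comparator_excludes_outside_reports(self, synthetic_reports):
        design = ComparisonDesign(
            "nivo vs pembro", Selector("label", "nivolumab"),
            Selector("label", "pembrolizumab"))
        table = build_contingency(synthetic_reports, design)
        full = build_contingency(
            synthetic_reports, ComparisonDesign("nivo", Selector("label", "nivolumab")))
        assert table.n_total < full.n_total
        assert table.a == full.a and table.b == full.b

    def test_cells_match_generator_ledger(self, synthetic_quarter,
                                          synthetic_reports):
        _cfg, _quarter, ledger = synthetic_quarter
        for design in default_designs():
            got = build_contingency(synthetic_reports, design)
            assert got == ledger.cells(design)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestSignalTable:
    def test_default_layout_cardinality(self, synthetic_reports):
        table = run_signal_table(synthetic_reports)
        kinds = table["row_kind"].value_counts().to_dict()
        assert kinds["drug"] == 8
        assert kinds["class"] == 3
        assert kinds["combination"] == 3
        assert kinds["comparison"] == 4

    def test_subgroup_rows_carry_no_ic(self, synthetic_reports):
        table = run_signal_table(synthetic_reports)
        comparisons = table[table["row_kind"] == "comparison"]
        assert comparisons["ic"].isna().all()
        assert comparisons["ic025"].isna().all()

    def test_zero_case_row_is_empty_not_zero(self, synthetic_reports):
        table = run_signal_table(synthetic_reports).set_index("label")
        row = table.loc["Tremelimumab"]
        assert row["n"] == 0 and np.isnan(row["ror"]) and np.isnan(row["ic"])

    def test_model_results_surface(self, synthetic_reports):
        results = DisproportionalityModel(synthetic_reports).fit()
        assert len(results.table) == len(default_designs())
        text = results.summary()
        assert "Nivolumab" in text and "ror025" in text
        signals = results.signals
        assert set(signals["label"]) <= set(results.table["label"])

    def test_injected_association_detected(self, synthetic_reports):
        # generator injected a reporting-odds multiplier of 4 on nivolumab
        table = run_signal_table(synthetic_reports).set_index("label")
        row = table.loc["Nivolumab"]
        assert row["signal_ror"] and row["signal_ic"]
        assert row["ror"] > 2
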