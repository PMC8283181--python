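"""Case definition, deduplication, regimen classification and onset."""

import pandas as pd
import pytest

from faerspv.cohort import (ICI_CLASS, PERICARDIAL_PTS,
                            build_cohort, classify_regimen, compute_tto,
                            deduplicate, indication_group, is_pericardial_pt,
                            label_from_suspects, normalize_drug_name, tto_bin)
from faerspv.dates import FuzzyDate
from faerspv.io import DrugUse, SafetyReport
from faerspv.synth import default_config, generate_database
from faerspv.io import assemble_reports


def _report(pid="1", case="1", version=1, receipt=FuzzyDate(2019, 6, 1),
            event=None, drugs=(), reactions=("pericardial effusion",),
            outcomes=()):
    return SafetyReport(
        case_id=case, primary_id=pid, case_version=version,
        receipt_date=receipt, event_date=event, age_years=None, sex=None,
        region=None, reporter=None, drugs=list(drugs),
        reactions=set(reactions), outcomes=set(outcomes), indications=set(),
    )


def _drug(name, role="PS", start=None, start_day=None):
    return DrugUse(raw_name=name, active_ingredient=name, role=role, seq="1",
                   start=start, start_day=start_day)


class TestCaseDefinition:
    def test_pt_list_is_the_fifteen_term_family(self):
        assert len(PERICARDIAL_PTS) == 15
        assert len(set(PERICARDIAL_PTS.values())) == 15

    @pytest.mark.parametrize("pt, expected", [
        ("Cardiac tamponade", True),
        ("pericardial effusion", True),
        ("  PERICARDITIS  ", True),
        ("10034487", True),          # constrictive pericarditis, by code
        (10007610, True),
        ("myocarditis", False),
        ("pericarditis bacterial", False),
        ("", False),
    ])
    def test_is_pericardial_pt(self, pt, expected):
        assert is_pericardial_pt(pt) is expected

    @pytest.mark.parametrize("raw, generic", [
        ("OPDIVO", "nivolumab"),
        ("Nivolumab (10 mg/mL)", "nivolumab"),
        ("KEYTRUDA 25MG/ML", "pembrolizumab"),
        ("yervoy.", "ipilimumab"),
        ("tremelimumab", "tremelimumab"),
        ("aspirin", None),
        ("", None),
    ])
    def test_normalize_drug_name(self, raw, generic):
        assert normalize_drug_name(raw) == generic


class TestDeduplicate:
    def test_highest_version_wins(self):
        versions = [_report(pid=str(i), case="42", version=i) for i in (1, 2, 3)]
        kept = deduplicate(versions)
        assert len(kept) == 1 and kept[0].case_version == 3

    def test_distinct_cases_all_kept(self):
        kept = deduplicate([_report(pid="1", case="1"), _report(pid="2", case="2")])
        assert len(kept) == 2

    def test_tie_broken_by_receipt_then_primaryid(self):
        a = _report(pid="5", case="1", version=2, receipt=FuzzyDate(2019, 1, 1))
        b = _report(pid="3", case="1", version=2, receipt=FuzzyDate(2019, 6, 1))
        assert deduplicate([a, b])[0].primary_id == "3"
        c = _report(pid="9", case="1", version=2, receipt=FuzzyDate(2019, 6, 1))
        assert deduplicate([b, c])[0].primary_id == "9"

    def test_matches_brute_force_groupby_on_injected_duplicates(self):
        cfg = default_config(n_reports=1000, seed=None)
        cfg.duplicate_rate = 0.10
        quarter, _ = generate_database(cfg, seed=77)
        reports = assemble_reports(quarter)
        kept = deduplicate(reports)
        df = pd.DataFrame({
            "case": [r.case_id for r in reports],
            "version": [r.case_version for r in reports],
            "receipt": [r.receipt_date.sort_key for r in reports],
            "pid": [int(r.primary_id) for r in reports],
        })
        brute = (df.sort_values(["case", "version", "receipt", "pid"])
                   .groupby("case").tail(1))
        assert len(kept) == df["case"].nunique() == len(brute)
        assert {int(r.primary_id) for r in kept} == set(brute["pid"])


class TestRegimen:
    def test_named_combination(self):
        r = _report(drugs=[_drug("ipilimumab"), _drug("nivolumab", role="SS")])
        regimen = classify_regimen(r)
        assert regimen.label == "ipilimumab+nivolumab"
        assert regimen.strategy == "combination"

    def test_monotherapy(self):
        regimen = classify_regimen(_report(drugs=[_drug("Keytruda")]))
        assert regimen.label == "pembrolizumab"
        assert regimen.strategy == "anti-PD-1 mono"

    def test_unnamed_pair_is_other(self):
        r = _report(drugs=[_drug("nivolumab"), _drug("pembrolizumab", role="SS")])
        assert classify_regimen(r).label == "other-multi-ICI"
        assert classify_regimen(r).strategy == "other"

    def test_concomitant_ici_never_contributes(self):
        r = _report(drugs=[_drug("ipilimumab"), _drug("nivolumab", role="C")])
        assert classify_regimen(r).label == "ipilimumab"

    def test_no_suspect_ici_is_an_error(self):
        with pytest.raises(ValueError, match="no suspect ICI"):
            classify_regimen(_report(drugs=[_drug("aspirin")]))

    def test_label_determines_strategy(self):
        for drug, target in ICI_CLASS.items():
            regimen = label_from_suspects(frozenset({drug}))
            assert target in regimen.strategy.replace("anti-", "")


class TestTto:
    def test_day_arithmetic(self):
        d = _drug("nivolumab", start_day=FuzzyDate(2019, 1, 1))
        r = _report(event=FuzzyDate(2019, 2, 12), drugs=[d])
        assert compute_tto(r) == 42

    def test_negative_interval_is_missing(self):
        d = _drug("nivolumab", start_day=FuzzyDate(2019, 5, 1))
        r = _report(event=FuzzyDate(2019, 4, 1), drugs=[d])
        assert compute_tto(r) is None

    def test_month_precision_start_is_missing(self):
        d = _drug("nivolumab", start=FuzzyDate(2019, 5))
        r = _report(event=FuzzyDate(2019, 6, 1), drugs=[d])
        assert compute_tto(r) is None

    def test_earliest_suspect_start_used(self):
        d1 = _drug("ipilimumab", start_day=FuzzyDate(2019, 3, 1))
        d2 = _drug("nivolumab", role="SS", start_day=FuzzyDate(2019, 1, 1))
        r = _report(event=FuzzyDate(2019, 1, 31), drugs=[d1, d2])
        assert compute_tto(r) == 30

    @pytest.mark.parametrize("days, label", [
        (0, "0-30"), (30, "0-30"), (31, "31-60"), (60, "31-60"),
        (61, "61-90"), (90, "61-90"), (91, "91-180"), (180, "91-180"),
        (181, ">180"), (5000, ">180"), (None, None),
    ])
    def test_bins_closed_on_the_left(self, days, label):
        assert tto_bin(days) == label


class TestIndicationGrouping:
    @pytest.mark.parametrize("terms, group", [
        ({"non-small cell lung cancer"}, "Lung cancer"),
        ({"malignant melanoma"}, "Melanoma"),
        ({"hodgkin's disease unspecified", "lymphoma"},
         "Hematological cancer and lymphoma"),
        ({"renal cell carcinoma"}, "Tumors of urinary system"),
        ({"sarcoma"}, "Other indications"),
        ({"product used for unknown indication"}, "Unknown or missing"),
        (set(), "Unknown or missing"),
    ])
    def test_keyword_map(self, terms, group):
        assert indication_group(terms) == group

    def test_specific_group_beats_generic(self):
        assert indication_group({"malignant neoplasm", "breast cancer"}) == \
            "Breast cancer"


class TestBuildCohort:
    def test_inclusion_and_suspect_role_rule(self):
        included = _report(case="a", drugs=[_drug("nivolumab")])
        concomitant_only = _report(
            case="b", drugs=[_drug("nivolumab", role="C")],
            reactions={"pericarditis"})
        no_event = _report(case="c", drugs=[_drug("nivolumab")],
                           reactions={"nausea"})
        cohort = build_cohort([included, concomitant_only, no_event])
        assert len(cohort) == 1
        assert cohort.records[0].report.case_id == "a"
        assert cohort.provenance["reports_in"] == 3

    def test_multiple_pericardial_pts_count_once(self):
        r = _report(drugs=[_drug("nivolumab")],
                    reactions={"pericarditis", "cardiac tamponade"})
        assert len(build_cohort([r])) == 1

    def test_empty_input_gives_valid_empty_cohort(self):
        cohort = build_cohort([])
        assert len(cohort) == 0 and cohort.provenance["cases"] == 0

    def test_idempotent_on_own_reports(self, synthetic_reports):
        cohort = build_cohort(synthetic_reports)
        again = build_cohort([rec.report for rec in cohort])
        assert len(again) == len(cohort)
        assert [(r.report.case_id, r.regimen.label, r.tto_days, r.fatal)
                for r in again] == \
               [(r.report.case_id, r.regimen.label, r.tto_days, r.fatal)
                for r in cohort]

    def test_strategy_partition_sums_to_cohort(self, synthetic_reports):
        cohort = build_cohort(synthetic_reports)
        strategies = ["anti-PD-1 mono", "anti-PD-L1 mono", "anti-CTLA-4 mono",
                      "combination", "other"]
        counts = {s: 0 for s in strategies}
        for rec in cohort:
            counts[rec.regimen.strategy] += 1
        assert sum(counts.values()) == len(cohort)

    def test_bin_counts_sum_to_documented(self, synthetic_reports):
        cohort = build_cohort(synthetic_reports)
        n_missing = sum(1 for r in cohort if r.tto_days is None)
        n_binned = sum(1 for r in cohort if r.tto_bin is not None)
        assert n_binned == len(cohort) - n_missing

    def test_synthetic_case_count_matches_ledger(self, synthetic_quarter,
                                                 synthetic_reports):
        _cfg, _quarter, ledger = synthetic_quarter
        cohort = build_cohort(synthetic_reports)
        truth = ledger.unique_cases
        expected = int((truth["pericardial"] &
                        truth["regimen_label"].notna()).sum())
        assert len(cohort) == expected
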