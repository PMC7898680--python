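import numpy as np
import pytest

from pvmlsd import (
    DegenerateDataError,
    IntegrityError,
    ReportSet,
    TermLookupError,
    build_input_dataset,
    contingency_table,
    covariate_counts,
)
from pvmlsd.features import COVARIATE_FEATURES, COVARIATE_NAMES

from conftest import make_report

COMPARATORS = {"COMP1", "COMP2"}


def brute_force_cells(reports, drug, ae, comparators):
    a = b = c = d = 0
    for r in reports:
        if drug in r.suspected_drugs:
            a, b = (a + 1, b) if ae in r.ae_terms else (a, b + 1)
        elif r.suspected_drugs & comparators:
            c, d = (c + 1, d) if ae in r.ae_terms else (c, d + 1)
    return a, b, c, d


class TestContingencyTable:
    def test_engineered_fixture_counts(self, contingency_reports):
        t = contingency_table(contingency_reports, "DRUG", "P1", COMPARATORS)
        assert (t.a, t.b, t.c, t.d) == (3, 2, 1, 2)
        assert (t.a, t.b, t.c, t.d) == brute_force_cells(
            contingency_reports, "DRUG", "P1", COMPARATORS
        )

    def test_dual_exposure_counts_toward_study_row_only(self, contingency_reports):
        # r3 names DRUG and COMP1; total counted reports must equal 8 (each once)
        t = contingency_table(contingency_reports, "DRUG", "P1", COMPARATORS)
        assert t.n == 8

    def test_no_comparator_reports_is_still_valid(self):
        rs = ReportSet([make_report("x", ["DRUG"], ["P1"]), make_report("y", ["DRUG"], ["P2"])])
        t = contingency_table(rs, "DRUG", "P1", COMPARATORS)
        assert (t.c, t.d) == (0, 0)

    def test_no_relevant_reports_is_degenerate(self):
        rs = ReportSet([make_report("x", ["OTHER"], ["P1"])])
        with pytest.raises(DegenerateDataError):
            contingency_table(rs, "DRUG", "P1", COMPARATORS)

    def test_drug_cannot_be_its_own_comparator(self, contingency_reports):
        with pytest.raises(IntegrityError):
            contingency_table(contingency_reports, "DRUG", "P1", {"DRUG"})


class TestCovariateCounts:
    def test_sex_counts_over_a_reports(self, contingency_reports):
        counts = covariate_counts(contingency_reports, "DRUG", "P1")
        assert counts["sex_male"] == 2 and counts["sex_female"] == 1

    def test_unknown_category_contributes_to_no_bucket(self, contingency_reports):
        # r5 is the only (DRUG, P3) report and has unknown occupation
        counts = covariate_counts(contingency_reports, "DRUG", "P3")
        assert all(counts[f] == 0 for f in COVARIATE_FEATURES["reporter_occupation"])
        assert counts["sex_male"] == 1  # still counted in families it does report

    def test_randomized_fixture_matches_exhaustive_tally(self):
        rng = np.random.default_rng(42)
        sexes = ("male", "female", "unknown")
        occs = ("physician", "nurse", "unknown", "consumer")
        reports = [
            make_report(
                f"r{i}",
                [rng.choice(["DRUG", "COMP1"])],
                ["P1"] if rng.random() < 0.5 else ["P2"],
                sex=str(rng.choice(sexes)),
                reporter_occupation=str(rng.choice(occs)),
                serious=bool(rng.random() < 0.3),
            )
            for i in range(60)
        ]
        counts = covariate_counts(ReportSet(reports), "DRUG", "P1")
        a_reports = [r for r in reports if "DRUG" in r.suspected_drugs and "P1" in r.ae_terms]
        assert counts["sex_female"] == sum(r.sex == "female" for r in a_reports)
        assert counts["occ_nurse"] == sum(r.reporter_occupation == "nurse" for r in a_reports)
        assert counts["serious_yes"] == sum(r.serious for r in a_reports)
        for family, names in COVARIATE_FEATURES.items():
            assert sum(counts[n] for n in names) <= len(a_reports)


class TestBuildInputDataset:
    def test_one_row_per_observed_term(self, contingency_reports, tiny_dict, tiny_catalog, tiny_reference):
        ds = build_input_dataset(
            contingency_reports, "DRUG", COMPARATORS, tiny_dict, tiny_reference, tiny_catalog
        )
        observed = {ae for r in contingency_reports if "DRUG" in r.suspected_drugs for ae in r.ae_terms}
        assert {row.ae for row in ds.rows} == observed
        assert len(ds.rows) == len(observed)

    def test_shared_report_counts_in_both_rows(self, contingency_reports, tiny_dict, tiny_catalog, tiny_reference):
        ds = build_input_dataset(
            contingency_reports, "DRUG", COMPARATORS, tiny_dict, tiny_reference, tiny_catalog
        )
        by_ae = {row.ae: row for row in ds.rows}
        # r2 names both P1 and P2: both a-cells include it
        assert by_ae["P1"].a == 3 and by_ae["P2"].a == 2

    def test_rows_match_brute_force_enumeration(self, contingency_reports, tiny_dict, tiny_catalog, tiny_reference):
        ds = build_input_dataset(
            contingency_reports, "DRUG", COMPARATORS, tiny_dict, tiny_reference, tiny_catalog
        )
        for row in ds.rows:
            assert (row.a, row.b, row.c, row.d) == brute_force_cells(
                contingency_reports, "DRUG", row.ae, COMPARATORS
            )
            assert row.soc == tiny_dict.soc(row.ae)

    def test_margins_identical_across_terms(self, contingency_reports, tiny_dict, tiny_catalog, tiny_reference):
        ds = build_input_dataset(
            contingency_reports, "DRUG", COMPARATORS, tiny_dict, tiny_reference, tiny_catalog
        )
        margins = {(row.a + row.b, row.c + row.d) for row in ds.rows}
        assert len(margins) == 1  # a+b and c+d do not depend on the term

    def test_irrelevant_report_changes_nothing(self, contingency_reports, tiny_dict, tiny_catalog, tiny_reference):
        ds1 = build_input_dataset(
            contingency_reports, "DRUG", COMPARATORS, tiny_dict, tiny_reference, tiny_catalog
        )
        extra = ReportSet(contingency_reports.reports + [make_report("r9", ["OTHER"], ["P1"])])
        ds2 = build_input_dataset(
            extra, "DRUG", COMPARATORS, tiny_dict, tiny_reference, tiny_catalog
        )
        assert ds1.rows == ds2.rows

    def test_term_missing_from_dictionary_is_named(self, tiny_dict, tiny_catalog, tiny_reference):
        rs = ReportSet([make_report("x", ["DRUG"], ["P1", "PX"])])
        with pytest.raises(TermLookupError, match="PX"):
            build_input_dataset(rs, "DRUG", COMPARATORS, tiny_dict, tiny_reference, tiny_catalog)

    def test_partitions_are_disjoint_and_exhaustive(self, contingency_reports, tiny_dict, tiny_catalog, tiny_reference):
        ds = build_input_dataset(
            contingency_reports, "DRUG", COMPARATORS, tiny_dict, tiny_reference, tiny_catalog
        )
        assert len(ds.gold_rows) + len(ds.unknown_rows) == len(ds.rows)
        assert len(COVARIATE_NAMES) == 18
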