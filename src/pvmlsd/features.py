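"""The novel input dataset: 23 features per drug–event pair.

For each distinct adverse-event term observed with the study drug we build
one row holding

* the four statistical features of the drug-by-event 2×2 report-count
  table (a, b, c, d),
* eighteen covariate report counts over the reports in cell ``a`` —
  sex (2), age band (3), seriousness (2), report type (3), reporter
  occupation (5), reporting institution (3),
* the event's system organ class (one categorical feature, one-hot
  expanded only at model-encoding time),

plus the pair's label status from the reference labels.

Counting conventions (report-level): a report with k event terms counts
toward k pairs' ``a`` cells but only once per cell; a report naming both
the study drug and a comparator is assigned to the study-drug row;
reports naming neither drug set are ignored.  Reports whose covariate
value is ``unknown`` contribute to ``a`` but to none of that family's
named buckets, so each family's counts sum to at most ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DegenerateDataError, IntegrityError, TermLookupError
from .labeling import (
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    UNKNOWN,
    LabelAssignment,
    ReferenceLabelSet,
    assign_label,
)
from .srs_data import DrugCatalog, Report, ReportSet, TermDictionary

# the 18 named covariate count features, grouped by family
COVARIATE_FEATURES: dict[str, tuple[str, ...]] = {
    "sex": ("sex_male", "sex_female"),
    "age_group": ("age_0_17", "age_18_64", "age_65plus"),
    "serious": ("serious_yes", "serious_no"),
    "report_type": ("type_spontaneous", "type_pms_study", "type_literature"),
    "reporter_occupation": (
        "occ_physician",
        "occ_pharmacist",
        "occ_nurse",
        "occ_other_health_professional",
        "occ_consumer",
    ),
    "institution": ("inst_pv_center", "inst_medical_institution", "inst_manufacturer"),
}
COVARIATE_NAMES: tuple[str, ...] = tuple(
    name for family in COVARIATE_FEATURES.values() for name in family
)
assert len(COVARIATE_NAMES) == 18

_CATEGORY_TO_FEATURE = {
    ("sex", "male"): "sex_male",
    ("sex", "female"): "sex_female",
    ("age_group", "0-17"): "age_0_17",
    ("age_group", "18-64"): "age_18_64",
    ("age_group", "65plus"): "age_65plus",
    ("report_type", "spontaneous"): "type_spontaneous",
    ("report_type", "pms_study"): "type_pms_study",
    ("report_type", "literature"): "type_literature",
    ("reporter_occupation", "physician"): "occ_physician",
    ("reporter_occupation", "pharmacist"): "occ_pharmacist",
    ("reporter_occupation", "nurse"): "occ_nurse",
    ("reporter_occupation", "other_health_professional"): "occ_other_health_professional",
    ("reporter_occupation", "consumer"): "occ_consumer",
    ("institution", "pv_center"): "inst_pv_center",
    ("institution", "medical_institution"): "inst_medical_institution",
    ("institution", "manufacturer"): "inst_manufacturer",
}


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts for one drug–event pair.

    a: study-drug reports with the event; b: study-drug reports without it;
    c: comparator-only reports with the event; d: comparator-only reports
    without it.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise IntegrityError("contingency cells must be nonnegative")
        if self.n == 0:
            raise DegenerateDataError("contingency table has N = 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FeatureVector:
    """One row of the novel input dataset: 23 features plus the label."""

    drug: str
    ae: str
    a: int
    b: int
    c: int
    d: int
    covariate_counts: dict[str, int]
    soc: str
    label: str  # label_positive | label_negative | unknown

    def __post_init__(self) -> None:
        missing = [n for n in COVARIATE_NAMES if n not in self.covariate_counts]
        if missing:
            raise IntegrityError(f"missing covariate count(s): {missing}")
        for family, names in COVARIATE_FEATURES.items():
            s = sum(self.covariate_counts[n] for n in names)
            if s > self.a:
                raise IntegrityError(
                    f"{family} counts sum to {s} > a={self.a} for ({self.drug}, {self.ae})"
                )


@dataclass
class NovelInputDataset:
    """All feature rows for one study drug, partitioned into the gold
    standard (labeled) rows and the unknown rows."""

    study_drug: str
    comparators: frozenset[str]
    rows: list[FeatureVector] = field(default_factory=list)

    @property
    def gold_rows(self) -> list[FeatureVector]:
        return [r for r in self.rows if r.label in (LABEL_POSITIVE, LABEL_NEGATIVE)]

    @property
    def unknown_rows(self) -> list[FeatureVector]:
        return [r for r in self.rows if r.label == UNKNOWN]

    def assignments(self) -> list[LabelAssignment]:
        return [LabelAssignment(r.drug, r.ae, r.label) for r in self.rows]


def _is_study(report: Report, drug: str) -> bool:
    return drug in report.suspected_drugs


def _is_comparator_only(report: Report, drug: str, comparators: frozenset[str]) -> bool:
    # dual-exposure reports count toward the study-drug row only
    return drug not in report.suspected_drugs and bool(
        report.suspected_drugs & comparators
    )


def contingency_table(
    reports: ReportSet | Iterable[Report],
    drug: str,
    ae: str,
    comparators: Iterable[str],
) -> ContingencyTable:
    """Build the 2×2 table of report counts for one drug–event pair."""
    comparators = frozenset(comparators)
    if drug in comparators:
        raise IntegrityError(f"study drug {drug!r} cannot be its own comparator")
    a = b = c = d = 0
    for r in reports:
        if _is_study(r, drug):
            if ae in r.ae_terms:
                a += 1
            else:
                b += 1
        elif _is_comparator_only(r, drug, comparators):
            if ae in r.ae_terms:
                c += 1
            else:
                d += 1
    if a + b + c + d == 0:
        raise DegenerateDataError(
            f"no report names {drug!r} or a comparator; table would be empty"
        )
    return ContingencyTable(a, b, c, d)


def covariate_counts(
    reports: ReportSet | Iterable[Report], drug: str, ae: str
) -> dict[str, int]:
    """The 18 named covariate counts over the reports in cell ``a``.

    ``unknown`` categories are excluded from the named buckets.
    """
    counts = {name: 0 for name in COVARIATE_NAMES}
    for r in reports:
        if not (_is_study(r, drug) and ae in r.ae_terms):
            continue
        counts["serious_yes" if r.serious else "serious_no"] += 1
        for family, value in (
            ("sex", r.sex),
            ("age_group", r.age_group),
            ("report_type", r.report_type),
            ("reporter_occupation", r.reporter_occupation),
            ("institution", r.institution),
        ):
            feat = _CATEGORY_TO_FEATURE.get((family, value))
            if feat is not None:
                counts[feat] += 1
    return counts


def build_input_dataset(
    reports: ReportSet,
    drug: str,
    comparators: Iterable[str],
    term_dict: TermDictionary,
    ref: ReferenceLabelSet,
    catalog: DrugCatalog,
) -> NovelInputDataset:
    """Assemble the full novel input dataset for one study drug.

    One row per distinct AE term observed with the study drug, carrying the
    2×2 counts, covariate counts, SOC and label status.
    """
    comparators = frozenset(comparators)
    observed_terms = sorted(
        {ae for r in reports if _is_study(r, drug) for ae in r.ae_terms}
    )
    if not observed_terms:
        raise DegenerateDataError(f"no report names study drug {drug!r}")
    rows = []
    for ae in observed_terms:
        if ae not in term_dict:
            raise TermLookupError(f"AE term {ae!r} not in dictionary")
        table = contingency_table(reports, drug, ae, comparators)
        rows.append(
            FeatureVector(
                drug=drug,
                ae=ae,
                a=table.a,
                b=table.b,
                c=table.c,
                d=table.d,
                covariate_counts=covariate_counts(reports, drug, ae),
                soc=term_dict.soc(ae),
                label=assign_label(drug, ae, ref, catalog).status,
            )
        )
    return NovelInputDataset(study_drug=drug, comparators=comparators, rows=rows)


def dataset_to_frame(dataset: NovelInputDataset) -> pd.DataFrame:
    """Serialize a dataset to a tidy frame (one row per pair, 23 feature
    columns plus the label)."""
    records = []
    for r in dataset.rows:
        rec = {"drug": r.drug, "ae": r.ae, "a": r.a, "b": r.b, "c": r.c, "d": r.d}
        rec.update({n: r.covariate_counts[n] for n in COVARIATE_NAMES})
        rec["soc"] = r.soc
        rec["label"] = r.label
        records.append(rec)
    cols = ["drug", "ae", "a", "b", "c", "d", *COVARIATE_NAMES, "soc", "label"]
    return pd.DataFrame(records, columns=cols)


def write_dataset(dataset: NovelInputDataset, path: str | Path, sep: str = "\t") -> None:
    dataset_to_frame(dataset).to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_dataset(
    path: str | Path, study_drug: str, comparators: Iterable[str], sep: str = "\t"
) -> NovelInputDataset:
    df = pd.read_csv(path, sep=sep, dtype={"drug": str, "ae": str, "soc": str, "label": str})
    rows = []
    for rec in df.to_dict("records"):
        rows.append(
            FeatureVector(
                drug=rec["drug"],
                ae=rec["ae"],
                a=int(rec["a"]),
                b=int(rec["b"]),
                c=int(rec["c"]),
                d=int(rec["d"]),
                covariate_counts={n: int(rec[n]) for n in COVARIATE_NAMES},
                soc=rec["soc"],
                label=rec["label"],
            )
        )
    return NovelInputDataset(
        study_drug=study_drug, comparators=frozenset(comparators), rows=rows
    )
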