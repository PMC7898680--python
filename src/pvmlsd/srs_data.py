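"""Domain model and file I/O for spontaneous adverse-event reports.

One :class:`Report` is an ICSR-like record: the suspected drugs, the
adverse-event preferred terms (PTs), and the reporting covariates a national
spontaneous reporting system collects (sex, age band, seriousness, report
type, reporter occupation, reporting institution).  Terms resolve to system
organ classes (SOCs) through a :class:`TermDictionary`; drugs resolve to ATC
codes and therapeutic class-mates through a :class:`DrugCatalog`.

Files are plain delimited text (TSV by default) with a declared header;
multi-valued drug/AE cells use a separator declared in the
:class:`TableDialect`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, IntegrityError

SEX_VALUES = ("male", "female", "unknown")
AGE_VALUES = ("0-17", "18-64", "65plus", "unknown")
REPORT_TYPE_VALUES = ("spontaneous", "pms_study", "literature")
OCCUPATION_VALUES = (
    "physician",
    "pharmacist",
    "nurse",
    "other_health_professional",
    "consumer",
    "unknown",
)
INSTITUTION_VALUES = ("pv_center", "medical_institution", "manufacturer", "unknown")

REPORT_COLUMNS = (
    "report_id",
    "drugs",
    "aes",
    "sex",
    "age_group",
    "serious",
    "report_type",
    "reporter_occupation",
    "institution",
)

# enum families that admit an explicit `unknown` bucket
_UNKNOWN_CAPABLE = {"sex", "age_group", "reporter_occupation", "institution"}


@dataclass(frozen=True)
class TableDialect:
    """Physical layout of report tables.

    ``map_unrecognized_to_unknown`` controls whether an enum string outside
    the fixed vocabulary is coerced to ``unknown`` (only for families that
    have an ``unknown`` member) or raises a :class:`FormatError`.
    """

    sep: str = "\t"
    multi_sep: str = ";"
    map_unrecognized_to_unknown: bool = False


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class Report:
    """One spontaneous individual case safety report."""

    report_id: str
    suspected_drugs: frozenset[str]
    ae_terms: frozenset[str]
    sex: str = "unknown"
    age_group: str = "unknown"
    serious: bool = False
    report_type: str = "spontaneous"
    reporter_occupation: str = "unknown"
    institution: str = "unknown"

    def __post_init__(self) -> None:
        if not self.suspected_drugs:
            raise IntegrityError(f"report {self.report_id!r}: at least one suspected drug required")
        if not self.ae_terms:
            raise IntegrityError(f"report {self.report_id!r}: at least one AE term required")
        for name, value, allowed in (
            ("sex", self.sex, SEX_VALUES),
            ("age_group", self.age_group, AGE_VALUES),
            ("report_type", self.report_type, REPORT_TYPE_VALUES),
            ("reporter_occupation", self.reporter_occupation, OCCUPATION_VALUES),
            ("institution", self.institution, INSTITUTION_VALUES),
        ):
            if value not in allowed:
                raise FormatError(
                    f"report {self.report_id!r}: {name}={value!r} not in {allowed}"
                )


@dataclass(frozen=True)
class TermDictionary:
    """Preferred-term code -> (display name, system-organ-class code)."""

    entries: Mapping[str, tuple[str, str]]

    def __contains__(self, pt_code: str) -> bool:
        return pt_code in self.entries

    def soc(self, pt_code: str) -> str:
        return self.entries[pt_code][1]

    def name(self, pt_code: str) -> str:
        return self.entries[pt_code][0]

    @property
    def soc_codes(self) -> tuple[str, ...]:
        """The closed, sorted list of SOC codes this dictionary spans."""
        return tuple(sorted({soc for _, soc in self.entries.values()}))


@dataclass(frozen=True)
class DrugCatalog:
    """Drug code -> (ATC code, mechanism tag, same-therapeutic-class drugs).

    Class-mates share the first five ATC characters and the mechanism tag;
    the relation is symmetric and never includes the drug itself.
    """

    entries: Mapping[str, tuple[str, str, frozenset[str]]]

    def __post_init__(self) -> None:
        for drug, (atc, mech, mates) in self.entries.items():
            if drug in mates:
                raise IntegrityError(f"drug {drug!r}: same_class must be irreflexive")
            for mate in mates:
                if mate in self.entries:
                    m_atc, m_mech, m_mates = self.entries[mate]
                    if drug not in m_mates:
                        raise IntegrityError(
                            f"same_class not symmetric: {drug!r} lists {mate!r} but not conversely"
                        )
                    if m_atc[:5] != atc[:5] or m_mech != mech:
                        raise IntegrityError(
                            f"class-mates {drug!r}/{mate!r} differ in ATC5 or mechanism"
                        )

    def __contains__(self, drug_code: str) -> bool:
        return drug_code in self.entries

    def class_mates(self, drug_code: str) -> frozenset[str]:
        return self.entries[drug_code][2]

    def atc(self, drug_code: str) -> str:
        return self.entries[drug_code][0]


@dataclass
class ReportSet:
    """Ordered collection of reports with provenance metadata."""

    reports: list[Report]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.reports:
            raise IntegrityError("ReportSet must be nonempty")
        seen: set[str] = set()
        for r in self.reports:
            if r.report_id in seen:
                raise IntegrityError(f"duplicate report_id {r.report_id!r}")
            seen.add(r.report_id)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)


def _parse_enum(value: str, allowed: tuple[str, ...], family: str, dialect: TableDialect) -> str:
    if value in allowed:
        return value
    if dialect.map_unrecognized_to_unknown and family in _UNKNOWN_CAPABLE:
        return "unknown"
    raise FormatError(f"unrecognized {family} value {value!r}")


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in ("yes", "true", "1"):
        return True
    if v in ("no", "false", "0"):
        return False
    raise FormatError(f"unrecognized serious value {value!r}")


def read_reports(path: str | Path, dialect: TableDialect = DEFAULT_DIALECT) -> ReportSet:
    """Read a report table into a validated :class:`ReportSet`.

    Raises :class:`FormatError` for a missing required column or an enum
    string outside the vocabulary (unless the dialect coerces to unknown),
    and :class:`IntegrityError` for duplicate report ids or empty drug/AE
    cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    reports = []
    for row in df.itertuples(index=False):
        drugs = frozenset(x for x in str(row.drugs).split(dialect.multi_sep) if x)
        aes = frozenset(x for x in str(row.aes).split(dialect.multi_sep) if x)
        reports.append(
            Report(
                report_id=str(row.report_id),
                suspected_drugs=drugs,
                ae_terms=aes,
                sex=_parse_enum(row.sex, SEX_VALUES, "sex", dialect),
                age_group=_parse_enum(row.age_group, AGE_VALUES, "age_group", dialect),
                serious=_parse_bool(row.serious),
                report_type=_parse_enum(
                    row.report_type, REPORT_TYPE_VALUES, "report_type", dialect
                ),
                reporter_occupation=_parse_enum(
                    row.reporter_occupation, OCCUPATION_VALUES, "reporter_occupation", dialect
                ),
                institution=_parse_enum(
                    row.institution, INSTITUTION_VALUES, "institution", dialect
                ),
            )
        )
    return ReportSet(reports, provenance={"source": str(path)})


def write_reports(
    reports: ReportSet, path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> None:
    """Write a report table deterministically (fixed column and row order).

    Multi-valued cells are sorted before joining, so two writes of the same
    ReportSet produce byte-identical files.
    """
    rows = []
    for r in reports:
        rows.append(
            {
                "report_id": r.report_id,
                "drugs": dialect.multi_sep.join(sorted(r.suspected_drugs)),
                "aes": dialect.multi_sep.join(sorted(r.ae_terms)),
                "sex": r.sex,
                "age_group": r.age_group,
                "serious": "yes" if r.serious else "no",
                "report_type": r.report_type,
                "reporter_occupation": r.reporter_occupation,
                "institution": r.institution,
            }
        )
    df = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    buf = io.StringIO()
    df.to_csv(buf, sep=dialect.sep, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue())


def read_term_dictionary(path: str | Path, sep: str = "\t") -> TermDictionary:
    """Read a PT->SOC dictionary (columns pt_code, pt_name, soc_code)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("pt_code", "pt_name", "soc_code"):
        if col not in df.columns:
            raise FormatError(f"missing required column(s): {col}")
    return TermDictionary(
        {row.pt_code: (row.pt_name, row.soc_code) for row in df.itertuples(index=False)}
    )


def write_term_dictionary(d: TermDictionary, path: str | Path, sep: str = "\t") -> None:
    rows = [
        {"pt_code": pt, "pt_name": name, "soc_code": soc}
        for pt, (name, soc) in sorted(d.entries.items())
    ]
    pd.DataFrame(rows, columns=["pt_code", "pt_name", "soc_code"]).to_csv(
        path, sep=sep, index=False, lineterminator="\n"
    )


def read_drug_catalog(path: str | Path, sep: str = "\t") -> DrugCatalog:
    """Read an ATC drug catalog (columns drug_code, atc, mechanism, class_mates)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("drug_code", "atc", "mechanism", "class_mates"):
        if col not in df.columns:
            raise FormatError(f"missing required column(s): {col}")
    entries = {}
    for row in df.itertuples(index=False):
        mates = frozenset(x for x in str(row.class_mates).split(";") if x)
        entries[row.drug_code] = (row.atc, row.mechanism, mates)
    return DrugCatalog(entries)


def write_drug_catalog(c: DrugCatalog, path: str | Path, sep: str = "\t") -> None:
    rows = [
        {
            "drug_code": drug,
            "atc": atc,
            "mechanism": mech,
            "class_mates": ";".join(sorted(mates)),
        }
        for drug, (atc, mech, mates) in sorted(c.entries.items())
    ]
    pd.DataFrame(rows, columns=["drug_code", "atc", "mechanism", "class_mates"]).to_csv(
        path, sep=sep, index=False, lineterminator="\n"
    )


def validate_report(
    report: Report, term_dict: TermDictionary, catalog: DrugCatalog
) -> list[str]:
    """Return one violation string per AE term or drug code not covered by
    the dictionary/catalog; empty list means fully covered."""
    violations = []
    for drug in sorted(report.suspected_drugs):
        if drug not in catalog:
            violations.append(f"drug {drug!r} not in catalog")
    for term in sorted(report.ae_terms):
        if term not in term_dict:
            violations.append(f"term {term!r} not in dictionary")
    return violations


def validate_reports(
    reports: Iterable[Report], term_dict: TermDictionary, catalog: DrugCatalog
) -> dict[str, list[str]]:
    """Validate a collection; returns {report_id: violations} for offenders only."""
    out = {}
    for r in reports:
        v = validate_report(r, term_dict, catalog)
        if v:
            out[r.report_id] = v
    return out
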