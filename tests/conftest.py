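import pytest

from pvmlsd import (
    DrugCatalog,
    ReferenceLabelSet,
    Report,
    ReportSet,
    TermDictionary,
)


def make_report(rid, drugs, aes, **kw):
    defaults = dict(
        sex="male",
        age_group="18-64",
        serious=False,
        report_type="spontaneous",
        reporter_occupation="physician",
        institution="pv_center",
    )
    defaults.update(kw)
    return Report(rid, frozenset(drugs), frozenset(aes), **defaults)


@pytest.fixture
def tiny_dict():
    return TermDictionary(
        {
            "P1": ("Nausea-like event", "S1"),
            "P2": ("Rash-like event", "S1"),
            "P3": ("Hepatitis-like event", "S2"),
            "P4": ("Pneumonitis-like event", "S2"),
            "P5": ("Colitis-like event", "S3"),
            "P6": ("Fatigue-like event", "S3"),
        }
    )


@pytest.fixture
def tiny_catalog():
    return DrugCatalog(
        {
            "DRUG": ("L01XC1", "checkpoint", frozenset({"MATE"})),
            "MATE": ("L01XC2", "checkpoint", frozenset({"DRUG"})),
            "COMP1": ("L01XA1", "cytotoxic", frozenset()),
            "COMP2": ("L01XA2", "cytotoxic", frozenset()),
        }
    )


@pytest.fixture
def contingency_reports():
    """8 reports engineered so (a,b,c,d) = (3,2,1,2) for (DRUG, P1)."""
    return ReportSet(
        [
            make_report("r1", ["DRUG"], ["P1"]),
            make_report("r2", ["DRUG"], ["P1", "P2"], sex="female"),
            make_report("r3", ["DRUG", "COMP1"], ["P1"]),  # dual exposure -> study row
            make_report("r4", ["DRUG"], ["P2"]),
            make_report("r5", ["DRUG"], ["P3"], reporter_occupation="unknown"),
            make_report("r6", ["COMP1"], ["P1", "P3"]),
            make_report("r7", ["COMP1"], ["P2"]),
            make_report("r8", ["COMP2"], ["P3", "P4"]),
        ]
    )


@pytest.fixture
def tiny_reference():
    return ReferenceLabelSet(
        frozenset(
            {
                ("DRUG", "P1"),
                ("DRUG", "P2"),
                ("MATE", "P3"),
            }
        ),
        {("DRUG", "P1"): ("AUTH_A",), ("DRUG", "P2"): ("AUTH_A",), ("MATE", "P3"): ("AUTH_B",)},
    )
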