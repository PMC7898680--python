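"""Gold-standard construction against regulatory reference labels.

Every observed (study drug, adverse event) pair is classified three ways:

* **label-positive** — the event is listed on the study drug's own label;
* **label-negative** — the event is listed neither on the study drug's label
  nor on the label of any drug in the same therapeutic class (same first
  five ATC characters and mechanism of action);
* **unknown** — everything else, i.e. absent from the study drug's label but
  present on at least one class-mate's label.

Label-positive and label-negative pairs form the gold standard used to
train and evaluate classifiers; the unknown pairs are the set scored for
new safety signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, IntegrityError, TermLookupError
from .srs_data import DrugCatalog

LABEL_POSITIVE = "label_positive"
LABEL_NEGATIVE = "label_negative"
UNKNOWN = "unknown"
STATUSES = (LABEL_POSITIVE, LABEL_NEGATIVE, UNKNOWN)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero upward, as summary tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_count_percent(count: int, total: int) -> str:
    """Render ``count`` as ``"31 (61%)"`` with a round-half-up integer percent."""
    pct = int(round_half_up(100.0 * count / total))
    return f"{count} ({pct}%)"


@dataclass(frozen=True)
class ReferenceLabelSet:
    """Union of (drug, preferred term) pairs listed on any consulted
    authority label, with per-entry source tags."""

    entries: frozenset[tuple[str, str]]
    sources: dict = None  # (drug, pt) -> tuple of authority tags

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.entries

    def terms_for(self, drug: str) -> frozenset[str]:
        return frozenset(pt for d, pt in self.entries if d == drug)


@dataclass(frozen=True)
class LabelAssignment:
    drug: str
    ae: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise IntegrityError(f"invalid status {self.status!r}")


def read_reference_labels(path: str | Path, sep: str = "\t") -> ReferenceLabelSet:
    """Read a reference label table (columns drug_code, pt_code, source)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("drug_code", "pt_code", "source"):
        if col not in df.columns:
            raise FormatError(f"missing required column(s): {col}")
    entries = set()
    sources: dict[tuple[str, str], tuple[str, ...]] = {}
    for row in df.itertuples(index=False):
        pair = (row.drug_code, row.pt_code)
        entries.add(pair)
        sources[pair] = tuple(sorted(set(sources.get(pair, ())) | {row.source}))
    return ReferenceLabelSet(frozenset(entries), sources)


def write_reference_labels(ref: ReferenceLabelSet, path: str | Path, sep: str = "\t") -> None:
    rows = []
    for drug, pt in sorted(ref.entries):
        tags = (ref.sources or {}).get((drug, pt), ("unspecified",))
        for tag in tags:
            rows.append({"drug_code": drug, "pt_code": pt, "source": tag})
    pd.DataFrame(rows, columns=["drug_code", "pt_code", "source"]).to_csv(
        path, sep=sep, index=False, lineterminator="\n"
    )


def assign_label(
    drug: str, ae: str, ref: ReferenceLabelSet, catalog: DrugCatalog
) -> LabelAssignment:
    """Classify one (drug, AE) pair by the three-way label rule.

    The result depends only on label membership of the pair itself and of
    the pair (class-mate, AE) over the drug's therapeutic class-mates.
    """
    if drug not in catalog:
        raise TermLookupError(f"drug {drug!r} not in catalog")
    if (drug, ae) in ref:
        status = LABEL_POSITIVE
    elif any((mate, ae) in ref for mate in catalog.class_mates(drug)):
        status = UNKNOWN
    else:
        status = LABEL_NEGATIVE
    return LabelAssignment(drug, ae, status)


def build_gold_standard(
    pairs: Sequence[tuple[str, str]], ref: ReferenceLabelSet, catalog: DrugCatalog
) -> tuple[list[LabelAssignment], list[LabelAssignment]]:
    """Partition observed pairs into (gold standard, unknowns).

    Gold = label-positive plus label-negative assignments; unknowns are the
    remaining pairs scored for new signals.  The partition is exhaustive
    and disjoint.
    """
    if not pairs:
        raise IntegrityError("pair list must be nonempty")
    if len(set(pairs)) != len(pairs):
        dupes = sorted({p for p in pairs if list(pairs).count(p) > 1})
        raise IntegrityError(f"duplicate pair(s): {dupes}")
    gold, unknowns = [], []
    for drug, ae in pairs:
        assignment = assign_label(drug, ae, ref, catalog)
        (unknowns if assignment.status == UNKNOWN else gold).append(assignment)
    return gold, unknowns


def label_distribution(assignments: Iterable[LabelAssignment]) -> pd.DataFrame:
    """Summary-table of counts and round-half-up integer percentages per status.

    Mirrors the drug-label distribution tables of spontaneous-reporting
    studies: total pairs, then label-positive / label-negative / unknown
    with ``n (p%)`` formatting.
    """
    assignments = list(assignments)
    if not assignments:
        raise IntegrityError("assignment list must be nonempty")
    total = len(assignments)
    rows = []
    counts = {s: sum(1 for a in assignments if a.status == s) for s in STATUSES}
    rows.append({"status": "total", "count": total, "formatted": format_count_percent(total, total)})
    for status in STATUSES:
        rows.append(
            {
                "status": status,
                "count": counts[status],
                "formatted": format_count_percent(counts[status], total),
            }
        )
    return pd.DataFrame(rows, columns=["status", "count", "formatted"])
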