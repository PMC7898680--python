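"""Synthetic spontaneous-reporting data with known ground truth.

The generator emulates the structure of a national spontaneous-reporting
database restricted to one study drug, its clinical-trial comparators and
its therapeutic class-mates: each report names one exposure drug (drawn
from marginal exposure probabilities), covariates drawn independently from
realistic category distributions, and a set of adverse-event terms drawn
independently per term with probability ``baseline × rate_ratio(drug,
term)``.  Planted (drug, term) pairs with rate ratio > 1 stand in for true
adverse drug reactions; everything else reports at its baseline rate.

A matching reference-label set is generated from the planted pairs: a
``label_noise`` fraction of planted pairs is deliberately *omitted* from
the study drug's label and placed on a class-mate's label instead, so
those pairs land in the unknown partition — they are the "unknown true
signals" that recovery experiments try to flag.  A handful of null terms
is also placed on class-mate labels so that all three label statuses
occur.

Everything is deterministic under the configuration seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ParameterError
from .labeling import ReferenceLabelSet, round_half_up, write_reference_labels
from .srs_data import (
    AGE_VALUES,
    INSTITUTION_VALUES,
    OCCUPATION_VALUES,
    REPORT_TYPE_VALUES,
    SEX_VALUES,
    DrugCatalog,
    Report,
    ReportSet,
    TermDictionary,
    write_drug_catalog,
    write_reports,
    write_term_dictionary,
)

_MAX_AE_PROB = 0.95

DEFAULT_COVARIATE_DISTS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.48, "female": 0.48, "unknown": 0.04},
    "age_group": {"0-17": 0.05, "18-64": 0.60, "65plus": 0.30, "unknown": 0.05},
    "serious": {"yes": 0.40, "no": 0.60},
    "report_type": {"spontaneous": 0.85, "pms_study": 0.12, "literature": 0.03},
    "reporter_occupation": {
        "physician": 0.35,
        "pharmacist": 0.15,
        "nurse": 0.15,
        "other_health_professional": 0.20,
        "consumer": 0.05,
        "unknown": 0.10,
    },
    "institution": {
        "pv_center": 0.45,
        "medical_institution": 0.35,
        "manufacturer": 0.15,
        "unknown": 0.05,
    },
}

_FAMILY_VALUES = {
    "sex": SEX_VALUES,
    "age_group": AGE_VALUES,
    "serious": ("yes", "no"),
    "report_type": REPORT_TYPE_VALUES,
    "reporter_occupation": OCCUPATION_VALUES,
    "institution": INSTITUTION_VALUES,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic reporting model."""

    n_reports: int
    study_drug: str
    comparators: tuple[str, ...]
    class_mates: tuple[str, ...]
    exposure_probs: Mapping[str, float]  # drug -> marginal exposure probability
    ae_baselines: Mapping[str, float]  # term -> baseline reporting probability
    soc_of: Mapping[str, str]  # term -> SOC code
    planted_pairs: tuple[tuple[str, str, float], ...]  # (drug, term, rate_ratio)
    covariate_dists: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_COVARIATE_DISTS
    )
    label_noise: float = 0.2
    n_classmate_only_labels: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ParameterError("n_reports must be positive")
        if not (0 <= self.label_noise < 1):
            raise ParameterError("label_noise must be in [0, 1)")
        total = sum(self.exposure_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"exposure probabilities must sum to 1 (got {total})")
        for term, p in self.ae_baselines.items():
            if not (0 < p < 1):
                raise ParameterError(f"baseline for {term!r} must be in (0, 1)")
        for drug, term, rr in self.planted_pairs:
            if rr < 1:
                raise ParameterError(f"rate_ratio for ({drug}, {term}) must be >= 1")


@dataclass
class GroundTruth:
    """What the simulator actually planted, for recovery checks."""

    planted_pairs: tuple[tuple[str, str, float], ...]
    reference: ReferenceLabelSet
    held_out_pairs: tuple[tuple[str, str], ...]  # planted but omitted from labels
    expected_counts: dict[tuple[str, str], float]  # expected cell-a count per planted pair


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study scenario: 20,000 reports; 90 terms over 10 SOCs;
    one study drug, six comparators, two class-mates; 30 planted pairs at
    rate ratio 5 (the remaining 60 terms are null); label_noise 0.2.

    Baseline reporting probabilities cycle through
    {0.005, 0.01, 0.02, 0.04} so planted and null pairs span rare and
    common events alike.
    """
    terms = [f"PT{i:04d}" for i in range(1, 91)]
    baselines = {t: (0.005, 0.01, 0.02, 0.04)[i % 4] for i, t in enumerate(terms)}
    soc_of = {t: f"SOC{(i // 9) + 1:02d}" for i, t in enumerate(terms)}
    study = "STUDY01"
    comparators = tuple(f"CMP{i:02d}" for i in range(1, 7))
    class_mates = ("CLS01", "CLS02")
    exposure = {study: 0.25}
    exposure.update({c: 0.10 for c in comparators})
    exposure.update({m: 0.075 for m in class_mates})
    planted = tuple((study, t, 5.0) for i, t in enumerate(terms) if i % 3 == 0)
    cfg = dict(
        n_reports=20_000,
        study_drug=study,
        comparators=comparators,
        class_mates=class_mates,
        exposure_probs=exposure,
        ae_baselines=baselines,
        soc_of=soc_of,
        planted_pairs=planted,
        label_noise=0.2,
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default scenario with every rate ratio at 1 (no true signals)."""
    return default_config(seed=seed, planted_pairs=(), **overrides)


def make_term_dictionary(config: SimulationConfig) -> TermDictionary:
    return TermDictionary(
        {t: (f"Synthetic event {t}", soc) for t, soc in sorted(config.soc_of.items())}
    )


def make_drug_catalog(config: SimulationConfig) -> DrugCatalog:
    entries = {}
    class_group = (config.study_drug, *config.class_mates)
    for i, drug in enumerate(class_group):
        mates = frozenset(d for d in class_group if d != drug)
        entries[drug] = (f"L01XC{i + 10}", "target_inhibitor", mates)
    for i, drug in enumerate(config.comparators):
        entries[drug] = (f"L01XA{i + 10}", "cytotoxic", frozenset())
    return DrugCatalog(entries)


def generate_reference_labels(config: SimulationConfig) -> tuple[ReferenceLabelSet, tuple]:
    """Build the synthetic regulatory reference-label set.

    Returns (reference, held_out_pairs).  Planted pairs become study-drug
    label entries except a seeded ``label_noise`` fraction, which moves to
    the first class-mate's label (so the pair classifies as unknown, never
    label-positive).  ``n_classmate_only_labels`` null terms also go on a
    class-mate's label.
    """
    rng = np.random.default_rng([config.seed, 1])
    planted = list(config.planted_pairs)
    n_holdout = int(round_half_up(config.label_noise * len(planted)))
    holdout_idx = set(
        rng.choice(len(planted), size=n_holdout, replace=False).tolist()
    ) if n_holdout else set()
    entries: set[tuple[str, str]] = set()
    sources: dict[tuple[str, str], tuple[str, ...]] = {}
    held_out = []
    mate = config.class_mates[0] if config.class_mates else None
    for i, (drug, term, _rr) in enumerate(planted):
        if i in holdout_idx:
            held_out.append((drug, term))
            if mate is not None:
                entries.add((mate, term))
                sources[(mate, term)] = ("SYNTH_AUTH_A",)
        else:
            entries.add((drug, term))
            sources[(drug, term)] = ("SYNTH_AUTH_A", "SYNTH_AUTH_B")
    planted_terms = {t for _, t, _ in planted}
    null_terms = sorted(t for t in config.ae_baselines if t not in planted_terms)
    n_extra = min(config.n_classmate_only_labels, len(null_terms))
    if mate is not None and n_extra:
        extra = rng.choice(len(null_terms), size=n_extra, replace=False)
        for j in sorted(extra.tolist()):
            entries.add((mate, null_terms[j]))
            sources[(mate, null_terms[j])] = ("SYNTH_AUTH_A",)
    return ReferenceLabelSet(frozenset(entries), sources), tuple(held_out)


def generate_reports(config: SimulationConfig) -> tuple[ReportSet, GroundTruth]:
    """Draw a full synthetic report set plus its ground truth.

    Per report: one exposure drug from the marginals; covariates
    independently from their category distributions; each AE term
    independently with probability ``baseline × rate_ratio`` capped at
    0.95.  Reports that drew zero AE terms are redrawn.  Deterministic
    under the config seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_reports
    drugs = sorted(config.exposure_probs)
    drug_probs = np.array([config.exposure_probs[d] for d in drugs])
    terms = sorted(config.ae_baselines)
    base = np.array([config.ae_baselines[t] for t in terms])

    rr = {(d, t): r for d, t, r in config.planted_pairs}
    # per-drug AE probability vectors
    prob_by_drug = {}
    for d in drugs:
        p = base.copy()
        for j, t in enumerate(terms):
            if (d, t) in rr:
                p[j] = p[j] * rr[(d, t)]
        if (p > _MAX_AE_PROB).any():
            warnings.warn(
                f"AE probability capped at {_MAX_AE_PROB} for drug {d}", stacklevel=2
            )
            p = np.minimum(p, _MAX_AE_PROB)
        prob_by_drug[d] = p

    drug_idx = rng.choice(len(drugs), size=n, p=drug_probs)
    prob_matrix = np.vstack([prob_by_drug[drugs[i]] for i in drug_idx])
    ae_matrix = rng.random((n, len(terms))) < prob_matrix
    # redraw reports that drew no AE at all (every report must carry >= 1 term)
    empty = np.flatnonzero(~ae_matrix.any(axis=1))
    guard = 0
    while empty.size:
        ae_matrix[empty] = rng.random((empty.size, len(terms))) < prob_matrix[empty]
        empty = empty[~ae_matrix[empty].any(axis=1)]
        guard += 1
        if guard > 10_000:  # pragma: no cover
            raise ParameterError("AE baselines too small; cannot draw nonempty reports")

    cov_draws = {}
    for family, values in _FAMILY_VALUES.items():
        dist = config.covariate_dists[family]
        vals = [v for v in values if v in dist]
        probs = np.array([dist[v] for v in vals])
        probs = probs / probs.sum()
        cov_draws[family] = [vals[i] for i in rng.choice(len(vals), size=n, p=probs)]

    reports = []
    for i in range(n):
        ae_set = frozenset(terms[j] for j in np.flatnonzero(ae_matrix[i]))
        reports.append(
            Report(
                report_id=f"R{i + 1:06d}",
                suspected_drugs=frozenset({drugs[drug_idx[i]]}),
                ae_terms=ae_set,
                sex=cov_draws["sex"][i],
                age_group=cov_draws["age_group"][i],
                serious=cov_draws["serious"][i] == "yes",
                report_type=cov_draws["report_type"][i],
                reporter_occupation=cov_draws["reporter_occupation"][i],
                institution=cov_draws["institution"][i],
            )
        )
    report_set = ReportSet(reports, provenance={"generator": "pvmlsd.simulate", "seed": config.seed})

    reference, held_out = generate_reference_labels(config)
    expected = {}
    for d, t, r in config.planted_pairs:
        p = min(config.ae_baselines[t] * r, _MAX_AE_PROB)
        expected[(d, t)] = n * config.exposure_probs[d] * p
    truth = GroundTruth(
        planted_pairs=config.planted_pairs,
        reference=reference,
        held_out_pairs=held_out,
        expected_counts=expected,
    )
    return report_set, truth


def write_simulation(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write reports, dictionary, catalog, and reference labels
    as TSVs (plus ground truth as JSON); returns the file paths."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports, truth = generate_reports(config)
    paths = {
        "reports": out / "reports.tsv",
        "dictionary": out / "term_dictionary.tsv",
        "catalog": out / "drug_catalog.tsv",
        "reference": out / "reference_labels.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_reports(reports, paths["reports"])
    write_term_dictionary(make_term_dictionary(config), paths["dictionary"])
    write_drug_catalog(make_drug_catalog(config), paths["catalog"])
    write_reference_labels(truth.reference, paths["reference"])
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "planted_pairs": [list(p) for p in truth.planted_pairs],
                "held_out_pairs": [list(p) for p in truth.held_out_pairs],
                "expected_counts": {f"{d}|{t}": v for (d, t), v in truth.expected_counts.items()},
            },
            indent=2,
        )
        + "\n"
    )
    return paths
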