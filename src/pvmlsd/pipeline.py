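"""End-to-end orchestration: labels → features → DPA → train → detect.

The protocol deliberately mirrors the published evaluation asymmetry: the
tree-ensemble classifiers are evaluated on the held-out 25% test split of
the gold standard, while the disproportionality methods are scored on the
*entire* gold standard (``dpa_on_test=True`` gives the symmetric variant).
The ROC score for a disproportionality method is its signal-defining
statistic — the ROR interval lower bound or IC025 — against the gold
labels.

Every stage's randomness derives from the single run seed, so two runs of
one configuration produce identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .dpa import adjusted_ror, crude_ror, dpa_signal, information_component
from .errors import InestimableError, ParameterError, SeparationError
from .features import (
    ContingencyTable,
    NovelInputDataset,
    build_input_dataset,
    dataset_to_frame,
    write_dataset,
)
from .evaluate import (
    SignalDecision,
    detect_signals,
    optimize_threshold,
    quadrant_comparison,
    roc_auc,
    threshold_metrics,
)
from .labeling import (
    ReferenceLabelSet,
    label_distribution,
    read_reference_labels,
)
from .srs_data import (
    DrugCatalog,
    ReportSet,
    TermDictionary,
    read_drug_catalog,
    read_reports,
    read_term_dictionary,
)
from .train import (
    Hyperparameters,
    default_grid,
    encode,
    predict_probability,
    smote_resample,
    split_train_test,
    tune_and_train,
)

log = logging.getLogger("pvmlsd.pipeline")


@dataclass
class RunConfig:
    """One MLSD run, either from in-memory objects or from file paths."""

    study_drug: str
    comparators: tuple[str, ...]
    algorithm: str = "gbm"  # model used for threshold search and detection
    hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)
    tune: bool = False  # grid-search via stratified 5-fold CV instead of fixed settings
    smote_k: int = 5
    smote_before_split: bool = False  # True reproduces the leakier published ordering
    split_fraction: float = 0.75
    seed: int = 0
    ror_mode: str = "crude"  # "crude" | "adjusted"
    adjusted_covariates: tuple[str, ...] = (
        "sex",
        "age_group",
        "serious",
        "report_type",
        "reporter_occupation",
        "institution",
    )
    dpa_on_test: bool = False
    # file inputs (used by run_pipeline / the CLI)
    reports_path: str | None = None
    dictionary_path: str | None = None
    catalog_path: str | None = None
    reference_path: str | None = None
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        hp = Hyperparameters(**raw.pop("hyperparameters", {}))
        raw["comparators"] = tuple(raw.get("comparators", ()))
        raw["adjusted_covariates"] = tuple(
            raw.get("adjusted_covariates", cls.adjusted_covariates)
        )
        return cls(hyperparameters=hp, **raw)


@dataclass
class RunReport:
    """Machine-readable summary of one run; consistent with emitted files."""

    study_drug: str
    n_pairs: int
    n_gold: int
    n_unknown: int
    label_table: list[dict]
    aucs: dict[str, float]
    dpa_evaluated_on: str  # "full_gold_standard" (published protocol) or "test_split"
    ml_evaluated_on: str  # always the held-out test split
    algorithm: str
    threshold: float
    threshold_metrics: dict
    signal_tables: dict[str, dict]
    seed: int
    hyperparameters: dict
    software: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _dpa_statistics(
    dataset: NovelInputDataset,
    reports: ReportSet,
    config: RunConfig,
    term_dict: TermDictionary,
    rows,
) -> dict[str, dict[tuple[str, str], tuple[float, bool]]]:
    """Per-pair (statistic, signal flag) for each DPA method over ``rows``."""
    out: dict[str, dict] = {"ror": {}, "ic": {}}
    for r in rows:
        table = ContingencyTable(r.a, r.b, r.c, r.d)
        if config.ror_mode == "adjusted":
            try:
                ror = adjusted_ror(
                    reports,
                    r.drug,
                    r.ae,
                    dataset.comparators,
                    covariates=config.adjusted_covariates,
                    term_dict=term_dict,
                )
            except (SeparationError, InestimableError):
                ror = crude_ror(table)  # documented fallback for inestimable pairs
        else:
            ror = crude_ror(table)
        ic = information_component(table)
        out["ror"][(r.drug, r.ae)] = (ror.ci_low, dpa_signal(ror))
        out["ic"][(r.drug, r.ae)] = (ic.ic025, dpa_signal(ic))
    return out


def run_study(
    reports: ReportSet,
    term_dict: TermDictionary,
    catalog: DrugCatalog,
    reference: ReferenceLabelSet,
    config: RunConfig,
) -> tuple[RunReport, NovelInputDataset, list[SignalDecision]]:
    """Execute the full MLSD protocol on in-memory inputs.

    Returns the run report, the novel input dataset, and the completed
    signal decisions on the unknown pairs (quadrants against the ROR
    criterion; the IC quadrants live in the report's signal tables).
    """
    dataset = build_input_dataset(
        reports, config.study_drug, config.comparators, term_dict, reference, catalog
    )
    log.info("stage=features rows=%d", len(dataset.rows))
    gold, unknown = dataset.gold_rows, dataset.unknown_rows
    log.info("stage=partition gold=%d unknown=%d", len(gold), len(unknown))
    label_table = label_distribution(dataset.assignments()).to_dict("records")

    soc_codes = term_dict.soc_codes
    enc_gold = encode(gold, soc_codes)
    train_idx, test_idx = split_train_test(
        enc_gold.X, enc_gold.y, fraction=config.split_fraction, seed=config.seed
    )
    log.info("stage=split train=%d test=%d", len(train_idx), len(test_idx))

    if config.smote_before_split:
        Xb, yb = smote_resample(enc_gold.X, enc_gold.y, k=config.smote_k, seed=config.seed)
        tr, te = split_train_test(Xb, yb, fraction=config.split_fraction, seed=config.seed)
        X_train, y_train = Xb[tr], yb[tr]
        X_test, y_test = Xb[te], yb[te]
        test_pairs = None  # synthetic rows have no pair identity
    else:
        X_train, y_train = smote_resample(
            enc_gold.X[train_idx], enc_gold.y[train_idx], k=config.smote_k, seed=config.seed
        )
        X_test, y_test = enc_gold.X[test_idx], enc_gold.y[test_idx]
        test_pairs = [enc_gold.pairs[i] for i in test_idx]
    log.info("stage=smote train_rows=%d", len(y_train))

    grid = default_grid(config.hyperparameters) if config.tune else None
    models = {}
    aucs: dict[str, float] = {}
    for algo in ("gbm", "rf"):
        models[algo] = tune_and_train(
            X_train,
            y_train,
            algo=algo,
            hp=config.hyperparameters,
            grid=grid,
            columns=enc_gold.columns,
        )
        aucs[algo] = roc_auc(predict_probability(models[algo], X_test), y_test)
    log.info("stage=train auc_gbm=%.4f auc_rf=%.4f", aucs["gbm"], aucs["rf"])

    # DPA scored on the entire gold standard by default (published protocol)
    dpa_rows = gold if not config.dpa_on_test else (
        [gold[i] for i in test_idx] if test_pairs is not None else gold
    )
    dpa_gold = _dpa_statistics(dataset, reports, config, term_dict, dpa_rows)
    gold_labels = {(r.drug, r.ae): (1 if r.label == "label_positive" else 0) for r in gold}
    for method in ("ror", "ic"):
        stats = dpa_gold[method]
        scores = [stats[p][0] for p in stats]
        labels = [gold_labels[p] for p in stats]
        aucs[method] = roc_auc(scores, labels)
    dpa_scope = "test_split" if config.dpa_on_test else "full_gold_standard"
    log.info("stage=dpa scope=%s auc_ror=%.4f auc_ic=%.4f", dpa_scope, aucs["ror"], aucs["ic"])

    chosen = models[config.algorithm]
    test_scores = predict_probability(chosen, X_test)
    t_star = optimize_threshold(test_scores, y_test)
    metrics = threshold_metrics(test_scores, y_test, t_star)
    log.info("stage=threshold t=%.2f balanced_accuracy=%.4f", t_star, metrics.balanced_accuracy)

    signal_tables: dict[str, dict] = {}
    decisions_ror: list[SignalDecision] = []
    if unknown:
        enc_unknown = encode(unknown, soc_codes)
        raw_decisions = detect_signals(chosen, enc_unknown, t_star)
        dpa_unknown = _dpa_statistics(dataset, reports, config, term_dict, unknown)
        for method in ("ror", "ic"):
            completed, summary = quadrant_comparison(raw_decisions, dpa_unknown[method])
            signal_tables[method] = summary
            if method == "ror":
                decisions_ror = completed
        log.info(
            "stage=detect unknown=%d mlsd_signals=%d",
            len(unknown),
            signal_tables["ror"]["mlsd_signals"],
        )
    else:
        log.info("stage=detect unknown=0")

    import sklearn
    import xgboost

    report = RunReport(
        study_drug=config.study_drug,
        n_pairs=len(dataset.rows),
        n_gold=len(gold),
        n_unknown=len(unknown),
        label_table=label_table,
        aucs={k: float(v) for k, v in aucs.items()},
        dpa_evaluated_on=dpa_scope,
        ml_evaluated_on="test_split",
        algorithm=config.algorithm,
        threshold=float(t_star),
        threshold_metrics=asdict(metrics),
        signal_tables=signal_tables,
        seed=config.seed,
        hyperparameters=asdict(chosen.hyperparameters),
        software={
            "pvmlsd": __version__,
            "xgboost": xgboost.__version__,
            "sklearn": sklearn.__version__,
        },
    )
    return report, dataset, decisions_ror


def run_pipeline(config: RunConfig) -> RunReport:
    """File-based entry point: load inputs, run the study, write artifacts."""
    for name in ("reports_path", "dictionary_path", "catalog_path", "reference_path"):
        if getattr(config, name) is None:
            raise ParameterError(f"run_pipeline requires {name}")
    reports = read_reports(config.reports_path)
    term_dict = read_term_dictionary(config.dictionary_path)
    catalog = read_drug_catalog(config.catalog_path)
    reference = read_reference_labels(config.reference_path)
    report, dataset, decisions = run_study(reports, term_dict, catalog, reference, config)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_dataset(dataset, out / "input_dataset.tsv")
        _write_decisions(decisions, out / "signals.tsv")
        (out / "run_report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
        (out / "run_report.txt").write_text(format_report(report))
    return report


def _write_decisions(decisions: Sequence[SignalDecision], path: Path) -> None:
    import pandas as pd

    pd.DataFrame([asdict(d) for d in decisions]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def format_report(report: RunReport) -> str:
    """Human-readable run summary."""
    lines = [
        f"MLSD run — study drug {report.study_drug} (seed {report.seed})",
        f"Pairs: {report.n_pairs} (gold {report.n_gold}, unknown {report.n_unknown})",
        "",
        "Label distribution:",
    ]
    for row in report.label_table:
        lines.append(f"  {row['status']:<16} {row['formatted']}")
    lines.append("")
    lines.append(
        f"AUC (ML on {report.ml_evaluated_on}, DPA on {report.dpa_evaluated_on}):"
    )
    for method, auc in report.aucs.items():
        lines.append(f"  {method:<4} {auc:.4f}")
    m = report.threshold_metrics
    lines.append("")
    lines.append(f"Chosen model: {report.algorithm}; optimal threshold t* = {report.threshold:.2f}")
    lines.append(
        "  accuracy {accuracy:.3f}  sensitivity {sensitivity:.3f}  "
        "specificity {specificity:.3f}".format(**m)
    )
    if report.signal_tables:
        lines.append("")
        lines.append("Signals among unknown pairs:")
        for method, tbl in report.signal_tables.items():
            lines.append(
                f"  vs {method.upper()}: MLSD {tbl['mlsd_formatted']}, "
                f"{method.upper()} {tbl['dpa_formatted']}, quadrants {tbl['quadrants']}"
            )
    return "\n".join(lines) + "\n"
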