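"""Performance evaluation, threshold optimization, and signal calling.

Predictive performance on the gold standard is the area under the ROC
curve.  The operating threshold is chosen by scanning t = 0.00, 0.01, …,
1.00 and maximizing the single-point ROC area, i.e. balanced accuracy
(sensitivity + specificity)/2; when several grid points tie, the highest
threshold wins.  A pair is an ML signal when its predicted probability is
≥ the threshold (inclusive, consistent with the ROR signal criterion).

Signals on the unknown pairs are cross-tabulated against the
disproportionality criterion into the four quadrants of the comparison
scatter: 1 = both methods signal, 2 = ML only, 3 = neither, 4 = DPA only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import DegenerateDataError, IntegrityError
from .labeling import format_count_percent
from .train import EncodedMatrix, TrainedModel, predict_probability

THRESHOLD_GRID = tuple(round(i / 100, 2) for i in range(101))


@dataclass(frozen=True)
class ThresholdMetrics:
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float | None  # None when no positive predictions
    npv: float | None  # None when no negative predictions
    balanced_accuracy: float


@dataclass(frozen=True)
class SignalDecision:
    drug: str
    ae: str
    mlsd_probability: float
    threshold: float
    is_mlsd_signal: bool
    dpa_statistic: float | None = None
    is_dpa_signal: bool | None = None
    quadrant: int | None = None


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC = P(random positive outscores random negative), ties counted 0.5."""
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def threshold_metrics(
    scores: Sequence[float], labels: Sequence[int], t: float
) -> ThresholdMetrics:
    """Confusion metrics at threshold ``t`` (prediction positive iff score ≥ t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pred = scores >= t
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ThresholdMetrics(
        threshold=t,
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        sensitivity=sens,
        specificity=spec,
        ppv=tp / (tp + fp) if (tp + fp) > 0 else None,
        npv=tn / (tn + fn) if (tn + fn) > 0 else None,
        balanced_accuracy=(sens + spec) / 2,
    )


def optimize_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Best operating threshold over the 101-point grid.

    Maximizes balanced accuracy; among tied maxima the highest threshold
    is selected.
    """
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    best_t, best_score = None, -np.inf
    for t in THRESHOLD_GRID:
        score = threshold_metrics(scores, labels, t).balanced_accuracy
        if score >= best_score:  # >= : ties resolve to the larger t
            best_score, best_t = score, t
    return best_t


def detect_signals(
    model: TrainedModel, unknown: EncodedMatrix, threshold: float
) -> list[SignalDecision]:
    """Score the unknown pairs and flag those at or above the threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise DegenerateDataError(f"threshold {threshold} outside [0, 1]")
    if len(unknown.pairs) == 0:
        return []
    proba = predict_probability(model, unknown)
    return [
        SignalDecision(
            drug=drug,
            ae=ae,
            mlsd_probability=float(p),
            threshold=threshold,
            is_mlsd_signal=bool(p >= threshold),
        )
        for (drug, ae), p in zip(unknown.pairs, proba)
    ]


def quadrant_comparison(
    decisions: Sequence[SignalDecision],
    dpa_results: Mapping[tuple[str, str], tuple[float, bool]],
) -> tuple[list[SignalDecision], dict]:
    """Complete each decision with its DPA statistic and quadrant.

    ``dpa_results`` maps (drug, ae) to (signal-defining statistic, signal
    flag) — the ROR interval lower bound or IC025.  Returns the completed
    decisions and a summary with the count and round-half-up percentage of
    unknown pairs flagged by each method and per-quadrant counts.
    """
    ml_pairs = {(d.drug, d.ae) for d in decisions}
    dpa_pairs = set(dpa_results)
    if ml_pairs != dpa_pairs:
        diff = sorted(ml_pairs ^ dpa_pairs)
        raise IntegrityError(f"pair sets differ between ML and DPA inputs: {diff}")
    completed = []
    for d in decisions:
        stat, flag = dpa_results[(d.drug, d.ae)]
        if d.is_mlsd_signal and flag:
            quadrant = 1
        elif d.is_mlsd_signal:
            quadrant = 2
        elif flag:
            quadrant = 4
        else:
            quadrant = 3
        completed.append(
            replace(d, dpa_statistic=float(stat), is_dpa_signal=bool(flag), quadrant=quadrant)
        )
    total = len(completed)
    n_ml = sum(1 for d in completed if d.is_mlsd_signal)
    n_dpa = sum(1 for d in completed if d.is_dpa_signal)
    summary = {
        "n_unknown": total,
        "mlsd_signals": n_ml,
        "mlsd_formatted": format_count_percent(n_ml, total) if total else "0 (0%)",
        "dpa_signals": n_dpa,
        "dpa_formatted": format_count_percent(n_dpa, total) if total else "0 (0%)",
        "quadrants": {q: sum(1 for d in completed if d.quadrant == q) for q in (1, 2, 3, 4)},
    }
    return completed, summary
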