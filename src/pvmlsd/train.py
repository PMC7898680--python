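"""Encoding, class balancing (SMOTE), splitting, and tree-ensemble training.

The gold-standard rows are encoded into a numeric matrix — the 4
statistical counts, the 18 covariate counts, and a fixed-width one-hot
block over the term dictionary's closed SOC list — and a binary label
vector (1 = label-positive).  SMOTE balances the minority class by
interpolating between nearest minority neighbors; the stratified 75/25
split, five-fold hyperparameter tuning, and gradient-boosted-tree /
random-forest fits all derive their randomness from one integer seed, so
a fixed seed reproduces the split, the balanced sample, the selected
hyperparameters and every prediction bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .errors import ParameterError, SchemaError, TermLookupError
from .features import COVARIATE_NAMES, FeatureVector
from .labeling import LABEL_POSITIVE, UNKNOWN, round_half_up

STAT_FEATURES = ("a", "b", "c", "d")


@dataclass(frozen=True)
class Hyperparameters:
    """Gradient-boosting settings (xgboost naming).

    Defaults follow the published configuration for the newer study drug;
    ``max_depth=6, colsample_bytree=0.7`` is the published setting for the
    older one.
    """

    eta: float = 0.01
    num_boost_rounds: int = 100
    max_depth: int = 4
    min_child_weight: float = 1.0
    colsample_bytree: float = 0.4
    gamma: float = 0.0
    random_state: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.eta <= 1):
            raise ParameterError("eta must be in (0, 1]")
        if self.num_boost_rounds < 1 or self.max_depth < 1:
            raise ParameterError("num_boost_rounds and max_depth must be >= 1")
        if not (0 < self.colsample_bytree <= 1):
            raise ParameterError("colsample_bytree must be in (0, 1]")
        if self.gamma < 0 or self.min_child_weight < 0:
            raise ParameterError("gamma and min_child_weight must be nonnegative")


@dataclass
class EncodedMatrix:
    """Numeric design matrix with its column schema and pair identities."""

    X: np.ndarray
    y: np.ndarray | None  # None for unknown (unlabeled) rows
    columns: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]  # (drug, ae) per row

    def subset(self, idx: np.ndarray) -> "EncodedMatrix":
        return EncodedMatrix(
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            columns=self.columns,
            pairs=tuple(self.pairs[i] for i in np.atleast_1d(idx)),
        )


@dataclass
class TrainedModel:
    algorithm: str  # "gbm" | "rf"
    model: object
    columns: tuple[str, ...]
    hyperparameters: Hyperparameters
    metadata: dict = field(default_factory=dict)


def encode(rows: Sequence[FeatureVector], soc_codes: Sequence[str]) -> EncodedMatrix:
    """Encode feature rows into a numeric matrix.

    Counts pass through unscaled; the SOC categorical becomes a one-hot
    block of fixed width over the closed ``soc_codes`` list, so train and
    test matrices built from the same dictionary always share a schema.
    Unknown-label rows yield ``y=None``; gold rows yield a 0/1 vector.
    """
    if not rows:
        raise ParameterError("cannot encode an empty row list")
    soc_codes = tuple(soc_codes)
    soc_index = {code: i for i, code in enumerate(soc_codes)}
    columns = (*STAT_FEATURES, *COVARIATE_NAMES, *(f"soc_{c}" for c in soc_codes))
    X = np.zeros((len(rows), len(columns)), dtype=float)
    labels = []
    for i, r in enumerate(rows):
        X[i, 0:4] = (r.a, r.b, r.c, r.d)
        for j, name in enumerate(COVARIATE_NAMES):
            X[i, 4 + j] = r.covariate_counts[name]
        if r.soc not in soc_index:
            raise TermLookupError(f"SOC code {r.soc!r} not in the closed SOC list")
        X[i, 4 + len(COVARIATE_NAMES) + soc_index[r.soc]] = 1.0
        labels.append(r.label)
    if all(l == UNKNOWN for l in labels):
        y = None
    else:
        y = np.array([1 if l == LABEL_POSITIVE else 0 for l in labels], dtype=int)
    return EncodedMatrix(
        X=X, y=y, columns=columns, pairs=tuple((r.drug, r.ae) for r in rows)
    )


def smote_resample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority over-sampling to exact class balance.

    Each synthetic point is ``x_i + u·(x_j − x_i)`` with ``u ~ U(0,1)`` and
    ``x_j`` one of the ``k`` nearest minority neighbors (Euclidean) of a
    randomly chosen minority point ``x_i``.  Original rows are retained
    unchanged and come first in the output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ParameterError("SMOTE requires exactly two classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min <= k:
        raise ParameterError(
            f"minority class has {n_min} rows; needs > k={k} neighbors — use a smaller k"
        )
    rng = np.random.default_rng(seed)
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)  # +1: self is its own nearest
    neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.random(size=n_new)
    xi = X_min[base]
    xj = X_min[neighbor_idx[base, pick]]
    synthetic = xi + u[:, None] * (xj - xi)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def split_train_test(
    X: np.ndarray, y: np.ndarray, fraction: float = 0.75, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split; returns (train_idx, test_idx).

    The training share of each class is ``round_half_up(n_class·fraction)``;
    the split is disjoint and exhaustive.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        cls_idx = np.flatnonzero(y == cls)
        if len(cls_idx) < 4:
            raise ParameterError(f"class {cls!r} has {len(cls_idx)} rows; need >= 4")
        perm = rng.permutation(cls_idx)
        n_train = int(round_half_up(len(cls_idx) * fraction))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def _make_estimator(algo: str, hp: Hyperparameters):
    if algo == "gbm":
        from xgboost import XGBClassifier

        return XGBClassifier(
            learning_rate=hp.eta,
            n_estimators=hp.num_boost_rounds,
            max_depth=hp.max_depth,
            min_child_weight=hp.min_child_weight,
            colsample_bytree=hp.colsample_bytree,
            gamma=hp.gamma,
            random_state=hp.random_state,
            n_jobs=1,
            eval_metric="logloss",
        )
    if algo == "rf":
        # published settings cover the boosted model only; classical forest defaults
        return RandomForestClassifier(
            n_estimators=500,
            max_features="sqrt",
            random_state=hp.random_state,
            n_jobs=1,
        )
    raise ParameterError(f"unknown algorithm {algo!r}; expected 'gbm' or 'rf'")


def default_grid(hp: Hyperparameters) -> list[Hyperparameters]:
    """Tuning grid spanning tree depth and column subsampling around the
    published values; declared order breaks score ties."""
    grid = []
    for depth in (3, 4, 5, 6):
        for colsample in (0.4, 0.7, 1.0):
            grid.append(replace(hp, max_depth=depth, colsample_bytree=colsample))
    return grid


def tune_and_train(
    X: np.ndarray,
    y: np.ndarray,
    algo: str = "gbm",
    hp: Hyperparameters | None = None,
    grid: Sequence[Hyperparameters] | None = None,
    columns: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit a classifier, optionally selecting hyperparameters by stratified
    five-fold cross-validated AUC.

    Candidates are scored by mean out-of-fold AUC; ties resolve to the
    first candidate in declared grid order; the winner is refit on the full
    training set.  Without a grid, ``hp`` is used directly.
    """
    hp = hp or Hyperparameters()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) != 2:
        raise ParameterError("training requires both classes present")
    chosen = hp
    cv_score = None
    if grid:
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=hp.random_state)
        folds = list(skf.split(X, y))
        for tr, te in folds:
            if len(np.unique(y[te])) < 2:
                raise ParameterError("degenerate fold: a class is absent from a fold")
        best = -np.inf
        for cand in grid:
            scores = []
            for tr, te in folds:
                est = _make_estimator(algo, cand)
                est.fit(X[tr], y[tr])
                scores.append(roc_auc_score(y[te], est.predict_proba(X[te])[:, 1]))
            mean = float(np.mean(scores))
            if mean > best:  # strict: first candidate wins ties
                best, chosen = mean, cand
        cv_score = best
    est = _make_estimator(algo, chosen)
    est.fit(X, y)
    return TrainedModel(
        algorithm=algo,
        model=est,
        columns=tuple(columns) if columns is not None else (),
        hyperparameters=chosen,
        metadata={"cv_auc": cv_score, "n_train": len(y), "grid_size": len(grid or [])},
    )


def predict_probability(model: TrainedModel, X: EncodedMatrix | np.ndarray) -> np.ndarray:
    """Predicted probability that each row is a true adverse drug reaction."""
    if isinstance(X, EncodedMatrix):
        if model.columns and model.columns != X.columns:
            diff = set(model.columns) ^ set(X.columns)
            raise SchemaError(f"column schema mismatch; differing columns: {sorted(diff)}")
        arr = X.X
    else:
        arr = np.asarray(X, dtype=float)
    proba = model.model.predict_proba(arr)[:, 1]
    return np.asarray(proba, dtype=float)
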