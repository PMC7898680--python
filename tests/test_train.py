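import numpy as np
import pytest

from pvmlsd import (
    FeatureVector,
    Hyperparameters,
    ParameterError,
    SchemaError,
    TermLookupError,
    encode,
    predict_probability,
    smote_resample,
    split_train_test,
    tune_and_train,
)
from pvmlsd.features import COVARIATE_NAMES
from pvmlsd.labeling import round_half_up
from pvmlsd.train import EncodedMatrix, default_grid

SOCS = ("S1", "S2", "S3", "S4", "S5")


def fv(ae, a, label, soc="S1"):
    cov = {n: 0 for n in COVARIATE_NAMES}
    cov["sex_male"] = min(a, 1)
    return FeatureVector("DRUG", ae, a, 10, 3, 50, cov, soc, label)


class TestEncode:
    def test_matrix_width_is_22_plus_soc_block(self):
        m = encode([fv("P1", 3, "label_positive"), fv("P2", 1, "label_negative", "S2")], SOCS)
        assert m.X.shape == (2, 22 + len(SOCS))
        assert len(m.columns) == 27

    def test_encoding_is_deterministic(self):
        rows = [fv("P1", 3, "label_positive"), fv("P2", 1, "label_negative", "S2")]
        m1, m2 = encode(rows, SOCS), encode(rows, SOCS)
        assert np.array_equal(m1.X, m2.X)
        assert m1.columns == m2.columns

    def test_schema_round_trip_on_column_names(self):
        m = encode([fv("P1", 3, "label_positive")], SOCS)
        assert m.columns[:4] == ("a", "b", "c", "d")
        assert m.columns[4 : 4 + 18] == COVARIATE_NAMES
        assert m.columns[22:] == tuple(f"soc_{s}" for s in SOCS)

    def test_unknown_soc_code_raises(self):
        with pytest.raises(TermLookupError):
            encode([fv("P1", 3, "label_positive", soc="S9")], SOCS)

    def test_unknown_rows_have_no_labels(self):
        m = encode([fv("P1", 3, "unknown")], SOCS)
        assert m.y is None


def imbalanced_data(seed=0, n_maj=40, n_min=10, dim=6):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_maj, dim)), rng.normal(3, 1, (n_min, dim))])
    y = np.array([0] * n_maj + [1] * n_min)
    return X, y


class TestSmote:
    def test_balances_classes_exactly(self):
        X, y = imbalanced_data()
        Xb, yb = smote_resample(X, y, k=5, seed=1)
        assert (yb == 0).sum() == (yb == 1).sum() == 40

    def test_originals_retained_unchanged(self):
        X, y = imbalanced_data()
        Xb, yb = smote_resample(X, y, k=5, seed=1)
        assert np.array_equal(Xb[: len(X)], X)
        assert np.array_equal(yb[: len(y)], y)

    def test_every_synthetic_point_is_a_minority_convex_combination(self):
        X, y = imbalanced_data()
        Xb, yb = smote_resample(X, y, k=5, seed=1)
        X_min = X[y == 1]
        for s in Xb[len(X):]:
            ok = False
            for i in range(len(X_min)):
                for j in range(len(X_min)):
                    if i == j:
                        continue
                    seg = X_min[j] - X_min[i]
                    denom = seg @ seg
                    if denom == 0:
                        continue
                    u = (s - X_min[i]) @ seg / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                        s, X_min[i] + u * seg, atol=1e-9
                    ):
                        ok = True
                        break
                if ok:
                    break
            assert ok, "synthetic point is not on a minority–minority segment"

    def test_same_seed_is_reproducible(self):
        X, y = imbalanced_data()
        out1 = smote_resample(X, y, k=5, seed=9)
        out2 = smote_resample(X, y, k=5, seed=9)
        assert np.array_equal(out1[0], out2[0]) and np.array_equal(out1[1], out2[1])

    def test_minority_smaller_than_k_is_rejected(self):
        X, y = imbalanced_data(n_min=4)
        with pytest.raises(ParameterError, match="smaller k"):
            smote_resample(X, y, k=5, seed=0)


class TestSplit:
    def test_75_25_class_arithmetic(self):
        y = np.array([1] * 80 + [0] * 20)
        X = np.zeros((100, 2))
        tr, te = split_train_test(X, y, fraction=0.75, seed=0)
        assert (y[tr] == 1).sum() == 60 and (y[tr] == 0).sum() == 15
        assert (y[te] == 1).sum() == 20 and (y[te] == 0).sum() == 5

    def test_split_is_disjoint_and_exhaustive(self):
        y = np.array([1] * 13 + [0] * 9)
        tr, te = split_train_test(np.zeros((22, 1)), y, seed=3)
        assert sorted(np.concatenate([tr, te]).tolist()) == list(range(22))

    @pytest.mark.parametrize("seed", range(10))
    def test_class_proportions_preserved_within_one_row(self, seed):
        y = np.array([1] * 37 + [0] * 16)
        tr, _ = split_train_test(np.zeros((53, 1)), y, fraction=0.75, seed=seed)
        for cls in (0, 1):
            n_cls = (y == cls).sum()
            assert abs((y[tr] == cls).sum() - round_half_up(0.75 * n_cls)) <= 1

    def test_tiny_class_is_rejected(self):
        y = np.array([1] * 3 + [0] * 10)
        with pytest.raises(ParameterError):
            split_train_test(np.zeros((13, 1)), y)


def separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n // 2, 4)), rng.normal(5, 0.3, (n // 2, 4))])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestTuneAndTrain:
    @pytest.mark.parametrize("algo", ["gbm", "rf"])
    def test_grid_of_one_equals_direct_fit(self, algo):
        X, y = separable_data()
        hp = Hyperparameters()
        direct = tune_and_train(X, y, algo=algo, hp=hp)
        gridded = tune_and_train(X, y, algo=algo, hp=hp, grid=[hp])
        assert np.allclose(
            predict_probability(direct, X), predict_probability(gridded, X)
        )

    def test_tuning_is_deterministic(self):
        X, y = separable_data()
        hp = Hyperparameters(random_state=200)
        grid = default_grid(hp)
        m1 = tune_and_train(X, y, algo="gbm", hp=hp, grid=grid)
        m2 = tune_and_train(X, y, algo="gbm", hp=hp, grid=grid)
        assert m1.hyperparameters == m2.hyperparameters
        assert np.array_equal(predict_probability(m1, X), predict_probability(m2, X))

    def test_separable_data_reaches_perfect_training_auc(self):
        from pvmlsd import roc_auc

        X, y = separable_data()
        model = tune_and_train(X, y, algo="gbm")
        assert roc_auc(predict_probability(model, X), y) == 1.0

    def test_single_class_is_rejected(self):
        with pytest.raises(ParameterError):
            tune_and_train(np.zeros((10, 2)), np.ones(10, dtype=int))

    def test_table_defaults_match_published_settings(self):
        hp = Hyperparameters()
        assert (hp.eta, hp.num_boost_rounds, hp.min_child_weight) == (0.01, 100, 1.0)
        assert (hp.gamma, hp.random_state) == (0.0, 200)
        assert (hp.max_depth, hp.colsample_bytree) in {(4, 0.4), (6, 0.7)}


class TestPredict:
    def test_duplicated_row_scores_identically(self):
        X, y = separable_data()
        model = tune_and_train(X, y, algo="gbm")
        p = predict_probability(model, np.vstack([X[0], X[0]]))
        assert p[0] == p[1]
        assert ((p >= 0) & (p <= 1)).all()

    def test_schema_mismatch_is_reported(self):
        X, y = separable_data()
        model = tune_and_train(X, y, algo="gbm", columns=("c1", "c2", "c3", "c4"))
        bad = EncodedMatrix(X, y, columns=("c1", "c2", "c3", "zz"), pairs=tuple(("D", f"t{i}") for i in range(len(y))))
        with pytest.raises(SchemaError, match="zz"):
            predict_probability(model, bad)
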