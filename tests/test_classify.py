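"""Classifier training, validation metrics, voting, sensitivity analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest

from condop.classify import (
    MODELS,
    ConfusionCounts,
    TrainConfig,
    compute_metrics,
    cross_dataset_test,
    cross_validate,
    evaluate_feature_subsets,
    sensitivity_importance,
    split_holdout,
    train_model,
    vote,
)
from condop.features import FEATURE_NAMES


def make_table(n_op=100, n_nop=100, seed=0, informative=True):
    """Class-separated feature table mimicking the operon/non-operon regime."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_op + n_nop):
        is_op = i < n_op
        if informative:
            feats = dict(
                igr_length=rng.normal(20, 15) if is_op else rng.normal(150, 60),
                cu_score=rng.normal(30, 4) if is_op else rng.normal(20, 4),
                diff_expr=abs(rng.normal(0, 0.4)) if is_op else abs(rng.normal(3.5, 1)),
                igr_expr=rng.normal(6, 1) if is_op else rng.normal(0.4, 0.4),
            )
        else:
            feats = {f: rng.normal() for f in FEATURE_NAMES}
        rows.append({"pair_id": f"p{i}", "label": "OP" if is_op else "NOP", **feats})
    return pd.DataFrame(rows)


class TestSplitHoldout:
    def test_stratified_counts(self):
        train, test = split_holdout(make_table(100, 100), TrainConfig(seed=5))
        assert len(test) == 60
        assert test["label"].value_counts().to_dict() == {"OP": 30, "NOP": 30}
        assert len(train) + len(test) == 200

    def test_same_seed_same_split(self):
        t = make_table(50, 50)
        a = split_holdout(t, TrainConfig(seed=9))
        b = split_holdout(t, TrainConfig(seed=9))
        assert a[0]["pair_id"].tolist() == b[0]["pair_id"].tolist()

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(test_fraction=0.0)

    def test_tiny_class_rejected(self):
        t = make_table(1, 50)
        with pytest.raises(ValueError):
            split_holdout(t, TrainConfig())


class TestMetrics:
    def test_hand_worked_counts(self):
        m = compute_metrics(ConfusionCounts(tp=9, fn=1, fp=2, tn=8))
        assert m["tpr"] == pytest.approx(0.9)
        assert m["ppv"] == pytest.approx(9 / 11)
        assert m["fpr_paper"] == pytest.approx(2 / 3)
        assert m["fpr_standard"] == pytest.approx(0.2)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["error_rate"] == pytest.approx(0.15)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=10, fn=0, fp=0, tn=10))
        assert m["accuracy"] == 1.0 and m["error_rate"] == 0.0

    def test_zero_denominator_is_nan_not_zero(self):
        m = compute_metrics(ConfusionCounts(tp=5, fn=5, fp=0, tn=0))
        assert np.isnan(m["fpr_standard"])
        m2 = compute_metrics(ConfusionCounts(tp=0, fn=0, fp=3, tn=7))
        assert np.isnan(m2["tpr"])

    def test_accuracy_plus_error_rate_is_one(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            c = ConfusionCounts(*rng.integers(0, 50, 4))
            if c.total == 0:
                continue
            m = compute_metrics(c)
            assert m["accuracy"] + m["error_rate"] == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))


class TestVote:
    @pytest.mark.parametrize("combo", list(itertools.product([0, 1], repeat=3)))
    def test_majority_rule_truth_table(self, combo):
        classes = ["OP" if c else "NOP" for c in combo]
        expected = "OP" if sum(combo) >= 2 else "NOP"
        assert vote(*classes) == expected

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            vote("OP", "maybe", "NOP")


class TestTrainModel:
    @pytest.mark.parametrize("kind", MODELS)
    def test_separable_data_fits_perfectly(self, kind):
        t = make_table(60, 60, seed=1)
        model = train_model(t, kind, TrainConfig(seed=2))
        X = t[list(FEATURE_NAMES)].to_numpy()
        y = (t["label"] == "OP").to_numpy(dtype=int)
        pred = model.predict(X)
        assert (pred == y).mean() >= 0.97

    @pytest.mark.parametrize("kind", MODELS)
    def test_same_seed_identical_predictions(self, kind):
        t = make_table(40, 40, seed=4)
        X = t[list(FEATURE_NAMES)].to_numpy()
        p1 = train_model(t, kind, TrainConfig(seed=7)).predict_proba(X)
        p2 = train_model(t, kind, TrainConfig(seed=7)).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        t = make_table(40, 40, seed=4)
        t["label"] = "OP"
        with pytest.raises(ValueError):
            train_model(t, "RF", TrainConfig())


class TestCrossValidate:
    def test_separable_data_perfect_report(self):
        t = make_table(40, 40, seed=6)
        cfg = TrainConfig(seed=3, cv_repeats=2, models=("RF",))
        rep = cross_validate(t, cfg)
        assert rep.accuracy_mean["RF"] >= 0.97
        assert rep.auc["RF"] >= 0.99

    def test_auc_trapezoid_equals_rank_statistic(self):
        t = make_table(40, 40, seed=6)
        cfg = TrainConfig(seed=3, cv_repeats=2, models=("RF",))
        rep = cross_validate(t, cfg)
        pooled = rep.pooled_scores["RF"]
        y, s = pooled[:, 0], pooled[:, 1]
        from scipy.stats import rankdata

        ranks = rankdata(s)
        n1, n0 = int(y.sum()), int((1 - y).sum())
        auc_rank = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert rep.auc["RF"] == pytest.approx(auc_rank, abs=1e-9)

    def test_label_shuffled_data_is_chance_level(self):
        t = make_table(200, 200, seed=8)
        rng = np.random.default_rng(12)
        t["label"] = rng.permutation(t["label"].to_numpy())
        cfg = TrainConfig(seed=3, cv_repeats=2, models=("RF",))
        rep = cross_validate(t, cfg)
        assert 0.4 <= rep.accuracy_mean["RF"] <= 0.6

    def test_metrics_recomputable_from_repeat_records(self):
        t = make_table(30, 30, seed=2)
        cfg = TrainConfig(seed=1, cv_repeats=2, models=("RF",))
        rep = cross_validate(t, cfg)
        accs = [r["accuracy"] for r in rep.per_repeat["RF"]]
        assert rep.accuracy_mean["RF"] == pytest.approx(np.mean(accs))
        assert rep.accuracy_sd["RF"] == pytest.approx(np.std(accs, ddof=1))


class _LinearModel:
    """Planted model: P(OP) = clip(intercept + sum(coef * x), 0, 1)."""

    classes_ = np.array([0, 1])

    def __init__(self, coef, intercept=0.5):
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = intercept

    def predict_proba(self, X):
        p = np.clip(self.intercept + X @ self.coef, 0.0, 1.0)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class TestSensitivity:
    def test_ignored_feature_has_zero_importance(self):
        t = make_table(50, 50, seed=5)
        model = _LinearModel([0.001, 0.0, 0.0, 0.0])
        imp = sensitivity_importance(model, t)["variance"]
        assert imp["cu_score"] == 0.0
        assert imp["diff_expr"] == 0.0
        assert imp["igr_length"] > 0.0

    def test_constant_model_all_zero(self):
        t = make_table(50, 50, seed=5)
        model = _LinearModel([0.0, 0.0, 0.0, 0.0])
        imp = sensitivity_importance(model, t)
        assert all(v == 0.0 for v in imp["variance"].values())
        assert all(v == 0.0 for v in imp["normalized"].values())

    def test_linear_response_matches_closed_form(self):
        t = make_table(50, 50, seed=5)
        b = 1e-4  # keep the response inside (0, 1) so clipping is inactive
        model = _LinearModel([0.0, 0.0, b, 0.0])
        levels = 7
        imp = sensitivity_importance(model, t, levels=levels)["variance"]
        col = t["diff_expr"].to_numpy()
        span = col.max() - col.min()
        step = span / (levels - 1)
        closed = b**2 * step**2 * (levels**2 - 1) / 12.0
        assert imp["diff_expr"] == pytest.approx(closed, abs=1e-9)


class TestFeatureSubsets:
    def test_only_transcriptomic_signal(self):
        rng = np.random.default_rng(10)
        n = 120
        rows = []
        for i in range(2 * n):
            is_op = i < n
            rows.append({
                "pair_id": f"p{i}",
                "label": "OP" if is_op else "NOP",
                "igr_length": rng.normal(50, 30),
                "cu_score": rng.normal(25, 5),
                "diff_expr": abs(rng.normal(0, 0.4)) if is_op else abs(rng.normal(3, 1)),
                "igr_expr": rng.normal(5, 1) if is_op else rng.normal(0.5, 0.5),
            })
        t = pd.DataFrame(rows)
        cfg = TrainConfig(seed=2, cv_repeats=2, models=("RF",))
        out = evaluate_feature_subsets(
            t, cfg, {"genomic": ("igr_length", "cu_score"),
                     "transcriptomic": ("diff_expr", "igr_expr")}
        )
        assert out["transcriptomic"]["RF"] > out["genomic"]["RF"] + 0.2

    def test_duplicate_subset_reported_twice(self):
        t = make_table(30, 30, seed=1)
        cfg = TrainConfig(seed=2, cv_repeats=1, models=("RF",))
        out = evaluate_feature_subsets(
            t, cfg, {"a": ("igr_length",), "b": ("igr_length",)}
        )
        assert out["a"] == out["b"]

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            evaluate_feature_subsets(make_table(30, 30), TrainConfig(), {"x": ()})


class TestCrossDataset:
    def test_reproducible_p_value(self):
        t = make_table(60, 60, seed=3)
        model = train_model(t, "RF", TrainConfig(seed=1))
        out1 = cross_dataset_test(model, t, make_table(60, 60, seed=9), seed=4)
        out2 = cross_dataset_test(model, t, make_table(60, 60, seed=9), seed=4)
        assert out1 == out2

    def test_small_table_rejected(self):
        t = make_table(60, 60, seed=3)
        model = train_model(t, "RF", TrainConfig(seed=1))
        with pytest.raises(ValueError, match="bootstrap"):
            cross_dataset_test(model, t, make_table(3, 3), seed=0)
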