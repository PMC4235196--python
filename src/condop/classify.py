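"""Train, validate and combine the three operon-pair classifiers.

A labelled feature table (OP = positive class, NOP = negative class) is used
to train a random forest, a single-hidden-layer neural network and an RBF
SVM.  NN/SVM hyperparameters are chosen by grid search with an internal
holdout validation split; features are standardized on the training data for
NN/SVM, the forest uses raw features.  Validation follows a 30% holdout plus
a 10x5 repeated stratified cross-validation; ROC curves are built from the
pooled held-out scores.  Predictions on unlabelled pairs (POP/EGP) are
combined with a simple majority voting scheme: a pair is an OP when at least
two of the three classifiers say so.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from condop.features import FEATURE_NAMES

__all__ = [
    "TrainConfig",
    "ConfusionCounts",
    "EvaluationReport",
    "VotePrediction",
    "split_holdout",
    "train_model",
    "cross_validate",
    "compute_metrics",
    "sensitivity_importance",
    "vote",
    "ensemble_predict",
    "evaluate_feature_subsets",
    "cross_dataset_test",
    "rf_refit_report",
    "table_to_xy",
    "FEATURE_SUBSETS",
]

MODELS = ("RF", "NN", "SVM")

# scikit-learn 1.9 deprecates SVC(probability=True); the ROC/voting contract
# needs per-class probabilities, so keep it and quiet the notice
warnings.filterwarnings(
    "ignore", message="The `probability` parameter was deprecated"
)

# pre-registered feature groups for the subset comparison
FEATURE_SUBSETS: dict[str, tuple[str, ...]] = {
    "all": FEATURE_NAMES,
    "genomic": ("igr_length", "cu_score"),
    "transcriptomic": ("diff_expr", "igr_expr"),
    "genomic+igr_expr": ("igr_length", "cu_score", "igr_expr"),
    "genomic+diff_expr": ("igr_length", "cu_score", "diff_expr"),
}


@dataclass
class TrainConfig:
    """Training / validation protocol parameters."""

    test_fraction: float = 0.30
    cv_folds: int = 5
    cv_repeats: int = 10
    seed: int = 0
    models: tuple[str, ...] = MODELS
    feature_subset: tuple[str, ...] = FEATURE_NAMES
    rf_trees: int = 500
    nn_hidden: tuple[int, ...] = (2, 4, 6, 8)
    svm_cost: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_gamma: tuple[float, ...] = (0.01, 0.1, 1.0)
    validation_fraction: float = 0.25  # internal holdout for the grid search

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        unknown = set(self.models) - set(MODELS)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class EvaluationReport:
    """Cross-validation results for one or more models."""

    per_repeat: dict[str, list[dict[str, float]]]
    accuracy_mean: dict[str, float]
    accuracy_sd: dict[str, float]
    auc: dict[str, float]
    roc_points: dict[str, np.ndarray]  # columns fpr, tpr
    pooled_scores: dict[str, np.ndarray]  # columns y_true, score
    fold_seeds: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class VotePrediction:
    pair_id: str
    rf_class: str
    nn_class: str
    svm_class: str
    final_class: str
    scores: tuple[float, float, float]  # per-model OP probability


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def table_to_xy(
    table: pd.DataFrame, features: Sequence[str] = FEATURE_NAMES
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and 0/1 labels (OP = 1) from a labelled table."""
    labelled = table[table["label"].isin(["OP", "NOP"])]
    X = labelled.loc[:, list(features)].to_numpy(dtype=float)
    y = (labelled["label"] == "OP").to_numpy(dtype=int)
    return X, y


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def split_holdout(
    table: pd.DataFrame, cfg: TrainConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random holdout of ``test_fraction`` of the labelled pairs."""
    labelled = table[table["label"].isin(["OP", "NOP"])]
    counts = labelled["label"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("both classes need >= 2 members for a stratified split")
    train, test = train_test_split(
        labelled,
        test_size=cfg.test_fraction,
        stratify=labelled["label"],
        random_state=cfg.seed % (2**31 - 1),
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


# ---------------------------------------------------------------------------
# model training
# ---------------------------------------------------------------------------

def _candidates(kind: str, cfg: TrainConfig, seed: int):
    if kind == "RF":
        return [RandomForestClassifier(n_estimators=cfg.rf_trees, random_state=seed)]
    if kind == "NN":
        return [
            Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "clf",
                        MLPClassifier(
                            hidden_layer_sizes=(h,),
                            solver="lbfgs",
                            max_iter=2000,
                            random_state=seed,
                        ),
                    ),
                ]
            )
            for h in cfg.nn_hidden
        ]
    if kind == "SVM":
        return [
            Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "clf",
                        SVC(
                            C=c,
                            gamma=g,
                            kernel="rbf",
                            probability=True,
                            random_state=seed,
                        ),
                    ),
                ]
            )
            for c in cfg.svm_cost
            for g in cfg.svm_gamma
        ]
    raise ValueError(f"unknown model kind {kind!r}")


def train_model(
    train_table: pd.DataFrame,
    model_kind: str,
    cfg: TrainConfig,
    seed: int | None = None,
):
    """Fit one classifier (with grid search for NN/SVM) on a labelled table.

    Returns a fitted estimator exposing ``predict_proba``; the OP probability
    is the column for class 1.  The forest needs no grid (its generalization
    error is estimated internally from out-of-bag data); NN/SVM candidates
    are ranked on an internal stratified validation holdout and the winner is
    refit on the full training table.
    """
    seed = cfg.seed if seed is None else seed
    X, y = table_to_xy(train_table, cfg.feature_subset)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    cands = _candidates(model_kind, cfg, seed)
    if len(cands) == 1:
        return cands[0].fit(X, y)
    X_fit, X_val, y_fit, y_val = train_test_split(
        X, y, test_size=cfg.validation_fraction, stratify=y,
        random_state=seed % (2**31 - 1),
    )
    best, best_acc = None, -1.0
    for cand in cands:
        cand.fit(X_fit, y_fit)
        acc = float((cand.predict(X_val) == y_val).mean())
        if acc > best_acc:
            best, best_acc = cand, acc
    # refit the winning configuration on the full training table
    from sklearn.base import clone

    return clone(best).fit(X, y)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The five evaluation metrics (plus the standard FPR).

    ``fpr_paper`` follows the printed formula FP/(FP+FN); ``fpr_standard`` is
    the conventional FP/(FP+TN).  Ratios with a zero denominator are NaN.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return {
        "tpr": ratio(c.tp, c.tp + c.fn),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "fpr_paper": ratio(c.fp, c.fp + c.fn),
        "fpr_standard": ratio(c.fp, c.fp + c.tn),
        "error_rate": (c.fp + c.fn) / c.total,
        "accuracy": (c.tp + c.tn) / c.total,
    }


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def _op_probability(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    return proba[:, classes.index(1)]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(train_table: pd.DataFrame, cfg: TrainConfig) -> EvaluationReport:
    """Repeated stratified k-fold CV (default 10x5) for each requested model.

    Per repeat a fresh seeded fold partition is drawn; per-fold metrics are
    averaged within the repeat; held-out OP probabilities of all folds are
    pooled into one ROC per model.
    """
    X, y = table_to_xy(train_table, cfg.feature_subset)
    if min((y == 1).sum(), (y == 0).sum()) < cfg.cv_folds:
        raise ValueError("each class needs >= cv_folds members")
    repeat_seeds = _spawn_seeds(cfg.seed, cfg.cv_repeats)
    per_repeat: dict[str, list[dict[str, float]]] = {m: [] for m in cfg.models}
    pooled: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {m: [] for m in cfg.models}
    df = pd.DataFrame(X, columns=list(cfg.feature_subset))
    df["label"] = np.where(y == 1, "OP", "NOP")

    for rep_seed in repeat_seeds:
        folds = _make_folds(y, cfg.cv_folds, rep_seed)
        fold_metrics: dict[str, list[dict[str, float]]] = {m: [] for m in cfg.models}
        for train_idx, test_idx in folds:
            sub = df.iloc[train_idx]
            X_te, y_te = X[test_idx], y[test_idx]
            for m in cfg.models:
                model = train_model(sub, m, cfg, seed=rep_seed)
                score = _op_probability(model, X_te)
                pred = (score >= 0.5).astype(int)
                fold_metrics[m].append(compute_metrics(_confusion(y_te, pred)))
                pooled[m].append((y_te, score))
        for m in cfg.models:
            agg = {}
            for k in fold_metrics[m][0]:
                vals = [fm[k] for fm in fold_metrics[m] if not math.isnan(fm[k])]
                agg[k] = float(np.mean(vals)) if vals else math.nan
            per_repeat[m].append(agg)

    accuracy_mean, accuracy_sd, auc, roc_points, pooled_scores = {}, {}, {}, {}, {}
    for m in cfg.models:
        accs = [r["accuracy"] for r in per_repeat[m]]
        accuracy_mean[m] = float(np.mean(accs))
        accuracy_sd[m] = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
        y_all = np.concatenate([t for t, _ in pooled[m]])
        s_all = np.concatenate([s for _, s in pooled[m]])
        fpr, tpr, _ = roc_curve(y_all, s_all)
        auc[m] = float(np.trapezoid(tpr, fpr))
        roc_points[m] = np.column_stack([fpr, tpr])
        pooled_scores[m] = np.column_stack([y_all, s_all])
    return EvaluationReport(
        per_repeat=per_repeat,
        accuracy_mean=accuracy_mean,
        accuracy_sd=accuracy_sd,
        auc=auc,
        roc_points=roc_points,
        pooled_scores=pooled_scores,
        fold_seeds=repeat_seeds,
    )


def _make_folds(y: np.ndarray, n_folds: int, seed: int, max_attempts: int = 10):
    """Seeded stratified folds; refolded (new seed) if a fold lacks a class."""
    for attempt in range(max_attempts):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=(seed + attempt) % (2**31 - 1))
        folds = list(skf.split(np.zeros_like(y), y))
        if all(len(np.unique(y[te])) == 2 for _, te in folds):
            return folds
    raise ValueError("could not build folds containing both classes")


def rf_refit_report(train_table: pd.DataFrame, cfg: TrainConfig) -> list[dict[str, float]]:
    """Paper-style RF protocol: ten refits, metrics from out-of-bag votes."""
    X, y = table_to_xy(train_table, cfg.feature_subset)
    out = []
    for seed in _spawn_seeds(cfg.seed, 10):
        rf = RandomForestClassifier(
            n_estimators=cfg.rf_trees, oob_score=True, random_state=seed
        ).fit(X, y)
        oob = rf.oob_decision_function_[:, list(rf.classes_).index(1)]
        pred = (oob >= 0.5).astype(int)
        out.append(compute_metrics(_confusion(y, pred)))
    return out


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

def sensitivity_importance(
    model,
    train_table: pd.DataFrame,
    features: Sequence[str] = FEATURE_NAMES,
    levels: int = 7,
) -> dict[str, dict[str, float]]:
    """1-D sensitivity analysis: vary one input over its observed range
    (``levels`` grid points), hold the others at their training means, and
    measure importance as the variance of the model's OP probability.

    Returns raw variances and the same normalized to sum 1.
    """
    X, _ = table_to_xy(train_table, features)
    means = X.mean(axis=0)
    raw: dict[str, float] = {}
    for j, name in enumerate(features):
        grid = np.linspace(X[:, j].min(), X[:, j].max(), levels)
        probe = np.tile(means, (levels, 1))
        probe[:, j] = grid
        responses = _op_probability(model, probe)
        raw[name] = float(np.var(responses))
    total = sum(raw.values())
    normalized = {k: (v / total if total > 0 else 0.0) for k, v in raw.items()}
    return {"variance": raw, "normalized": normalized}


# ---------------------------------------------------------------------------
# voting
# ---------------------------------------------------------------------------

def vote(rf_class: str, nn_class: str, svm_class: str) -> str:
    """Simple majority voting scheme: OP iff at least two OP votes."""
    votes = (rf_class, nn_class, svm_class)
    for v in votes:
        if v not in ("OP", "NOP"):
            raise ValueError(f"invalid class {v!r}")
    return "OP" if sum(v == "OP" for v in votes) >= 2 else "NOP"


def ensemble_predict(
    models: Mapping[str, object],
    table: pd.DataFrame,
    features: Sequence[str] = FEATURE_NAMES,
) -> list[VotePrediction]:
    """Classify each table row with all three models and majority-vote."""
    missing = set(MODELS) - set(models)
    if missing:
        raise ValueError(f"missing model output for {sorted(missing)}")
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    probs = {m: _op_probability(models[m], X) for m in MODELS}
    out = []
    for i, pair_id in enumerate(table["pair_id"]):
        classes = {m: ("OP" if probs[m][i] >= 0.5 else "NOP") for m in MODELS}
        out.append(
            VotePrediction(
                pair_id=pair_id,
                rf_class=classes["RF"],
                nn_class=classes["NN"],
                svm_class=classes["SVM"],
                final_class=vote(classes["RF"], classes["NN"], classes["SVM"]),
                scores=(float(probs["RF"][i]), float(probs["NN"][i]), float(probs["SVM"][i])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# feature subsets & cross-dataset transfer
# ---------------------------------------------------------------------------

def evaluate_feature_subsets(
    table: pd.DataFrame,
    cfg: TrainConfig,
    subsets: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, dict[str, float]]:
    """CV mean accuracy per feature subset x model, on identical folds.

    Folds depend only on the labels and the master seed, so every subset is
    evaluated on the same partitions (paired comparison).  A subset repeated
    under two names is computed once and reported twice.
    """
    subsets = dict(subsets) if subsets is not None else dict(FEATURE_SUBSETS)
    if any(len(f) == 0 for f in subsets.values()):
        raise ValueError("empty feature subset")
    cache: dict[tuple[str, ...], dict[str, float]] = {}
    out: dict[str, dict[str, float]] = {}
    for name, feats in subsets.items():
        key = tuple(feats)
        if key not in cache:
            sub_cfg = TrainConfig(
                **{**cfg.__dict__, "feature_subset": key}
            )
            report = cross_validate(table, sub_cfg)
            cache[key] = dict(report.accuracy_mean)
        out[name] = cache[key]
    return out


def cross_dataset_test(
    model,
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    n_bootstrap: int = 50,
    fraction: float = 0.70,
    seed: int = 0,
    features: Sequence[str] = FEATURE_NAMES,
) -> tuple[float, float, float]:
    """Accuracy of a fitted model on bootstrap samples of two datasets.

    ``n_bootstrap`` samples of ``fraction`` of each table are drawn with
    replacement; the two accuracy vectors are compared with a Welch t-test.
    Returns (mean accuracy on A, mean accuracy on B, p-value).
    """
    accs = []
    for i, table in enumerate((table_a, table_b)):
        X, y = table_to_xy(table, features)
        if len(y) < 10:
            raise ValueError("table too small for bootstrap (< 10 labelled pairs)")
        # per-row correctness once; bootstrap samples only re-index it
        correct = ((_op_probability(model, X) >= 0.5).astype(int) == y).astype(float)
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        size = max(1, int(round(fraction * len(y))))
        acc = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            acc[b] = correct[rng.integers(0, len(y), size=size)].mean()
        accs.append(acc)
    mean_a, mean_b = float(accs[0].mean()), float(accs[1].mean())
    if accs[0].std() == 0.0 and accs[1].std() == 0.0:
        # both accuracy vectors are constant (e.g. a separable table scored
        # perfectly): no within-sample variation, so the comparison carries
        # evidence only through the means
        p = 1.0 if mean_a == mean_b else 0.0
    else:
        _, p = stats.ttest_ind(accs[0], accs[1], equal_var=False)
    return mean_a, mean_b, float(p)
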