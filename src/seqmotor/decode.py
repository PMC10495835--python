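"""Feature selection, linear-SVM classification, cross-validation, online
simulation and behavioral timing summaries.

Mutual information between each feature (equal-width 10-bin discretization
over the training range) and the class label ranks the features; the top k
(k = 10 in the online configuration) are z-scored with fold-train
statistics and fed to a linear SVM with C = 1.  Offline evaluation uses
stratified 10-fold cross-validation; the online simulation fits every
model on blocks 1-6 once and classifies the two 40-trial feedback blocks
with fixed binary classifiers (LL-vs-RR, LR-vs-RL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core_io import TASKS, EventCode, group_trials, logger
from .spatial_features import (
    FeatureEpochSet,
    FeatureMatrix,
    SpatialFilterModel,
    extract_features,
    fit_spatial_models,
)


@dataclass
class DecoderConfig:
    """Classifier settings (linear SVM, penalty C, stratified k-fold CV)."""

    C: float = 1.0
    kernel: str = "linear"
    folds: int = 10
    k_features: int = 10
    n_bins: int = 10
    seed: int = 0
    n_dsp: int = 2
    n_trca: int = 3
    n_csp: int = 3
    shrinkage: float = 0.05

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class SelectionResult:
    """Mutual-information ranking of features (bits; ties by ascending index)."""

    mi_scores: np.ndarray
    ranking: np.ndarray
    selected: np.ndarray
    k: int
    binning: int


@dataclass
class ClassificationReport:
    """Pooled CV (or held-out) classification outcome."""

    fold_accuracies: list[float]           # percent
    mean_accuracy: float                   # percent, pooled trace/total
    confusion: np.ndarray                  # rows true, columns predicted
    class_order: tuple[str, ...]
    selected_features: list[np.ndarray] = field(default_factory=list)
    decisions: pd.DataFrame | None = None  # per-trial log (online runs)


# --------------------------------------------------------------------------
# mutual-information feature selection
# --------------------------------------------------------------------------

def discrete_mutual_information(x_bins: np.ndarray, y: np.ndarray) -> float:
    """Exact plug-in MI (bits) between two discrete label arrays."""
    xv, xi = np.unique(x_bins, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((len(xv), len(yv)))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def mutual_information_rank(features: FeatureMatrix | np.ndarray,
                            labels: np.ndarray | None = None,
                            n_bins: int = 10) -> SelectionResult:
    """Rank features by MI(feature; label) with equal-width binning.

    Each feature is discretized into ``n_bins`` equal-width bins over its
    observed (training) range; constant features score 0.  Ties are broken
    by ascending feature index.
    """
    if isinstance(features, FeatureMatrix):
        values = features.values
        labels = features.labels if labels is None else labels
    else:
        values = np.asarray(features, float)
    if labels is None:
        raise ValueError("labels are required")
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("MI ranking needs >= 2 classes")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n_feat = values.shape[1]
    scores = np.zeros(n_feat)
    for j in range(n_feat):
        col = values[:, j]
        lo, hi = col.min(), col.max()
        if hi <= lo:
            continue  # constant feature -> MI 0
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.clip(np.digitize(col, edges[1:-1]), 0, n_bins - 1)
        scores[j] = discrete_mutual_information(bins, labels)
    ranking = np.lexsort((np.arange(n_feat), -scores))
    return SelectionResult(scores, ranking, ranking.copy(), n_feat, n_bins)


def select_top_k(selection: SelectionResult, k: int) -> np.ndarray:
    """First ``k`` indices of the MI ranking."""
    if not 1 <= k <= len(selection.ranking):
        raise ValueError(f"k={k} outside [1, {len(selection.ranking)}]")
    return selection.ranking[:k].copy()


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def _class_order(labels: np.ndarray) -> tuple[str, ...]:
    present = set(labels.tolist())
    ordered = [t for t in TASKS if t in present]
    ordered += sorted(present - set(ordered))
    return tuple(ordered)


def _confusion(y_true, y_pred, order) -> np.ndarray:
    idx = {c: i for i, c in enumerate(order)}
    mat = np.zeros((len(order), len(order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[idx[t], idx[p]] += 1
    return mat


def _fit_predict(train_x, train_y, test_x, config: DecoderConfig,
                 k: int) -> tuple[np.ndarray, np.ndarray]:
    """MI selection + z-scoring + linear SVM, fitted on training rows only."""
    sel = mutual_information_rank(train_x, train_y, n_bins=config.n_bins)
    chosen = select_top_k(sel, min(k, train_x.shape[1]))
    scaler = StandardScaler().fit(train_x[:, chosen])
    clf = SVC(C=config.C, kernel=config.kernel)
    clf.fit(scaler.transform(train_x[:, chosen]), train_y)
    return clf.predict(scaler.transform(test_x[:, chosen])), chosen


def crossvalidate(features: FeatureMatrix | np.ndarray,
                  labels: np.ndarray | None = None,
                  config: DecoderConfig | None = None) -> ClassificationReport:
    """Stratified k-fold CV on a precomputed feature matrix.

    Within each fold the MI ranking, top-k selection, feature
    standardization and the SVM are all fitted on fold-train rows only;
    predictions are pooled into one confusion matrix.
    """
    config = config or DecoderConfig()
    if isinstance(features, FeatureMatrix):
        values = features.values
        labels = features.labels if labels is None else np.asarray(labels)
    else:
        values = np.asarray(features, float)
        labels = np.asarray(labels)
    order = _class_order(labels)
    counts = {c: int((labels == c).sum()) for c in order}
    low = {c: n for c, n in counts.items() if n < config.folds}
    if low:
        raise ValueError(f"per-class counts below fold count: {low}")
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    y = labels.astype(str)
    fold_acc, selected = [], []
    y_true_all, y_pred_all = [], []
    for train_idx, test_idx in skf.split(values, y):
        pred, chosen = _fit_predict(values[train_idx], y[train_idx],
                                    values[test_idx], config,
                                    config.k_features)
        selected.append(chosen)
        fold_acc.append(100.0 * np.mean(pred == y[test_idx]))
        y_true_all.extend(y[test_idx])
        y_pred_all.extend(pred)
    confusion = _confusion(y_true_all, y_pred_all, order)
    mean_acc = 100.0 * np.trace(confusion) / confusion.sum()
    return ClassificationReport(fold_acc, float(mean_acc), confusion, order,
                                selected_features=selected)


def crossvalidate_epochs(epochs: FeatureEpochSet,
                         config: DecoderConfig | None = None,
                         ) -> ClassificationReport:
    """Leakage-free end-to-end CV: the DCPM/TRCA/FBCSP bank is refitted on
    each fold's training trials before MI selection and the SVM."""
    config = config or DecoderConfig()
    labels = epochs.labels.astype(str)
    order = _class_order(epochs.labels)
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    fold_acc, selected = [], []
    y_true_all, y_pred_all = [], []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        assert not set(train_idx) & set(test_idx)  # structural leakage guard
        train = epochs.subset(train_idx)
        test = epochs.subset(test_idx)
        models = fit_spatial_models(train, n_dsp=config.n_dsp,
                                    n_trca=config.n_trca, n_csp=config.n_csp,
                                    shrinkage=config.shrinkage)
        f_train = extract_features(models, train)
        f_test = extract_features(models, test)
        pred, chosen = _fit_predict(f_train.values, labels[train_idx],
                                    f_test.values, config, config.k_features)
        selected.append(chosen)
        fold_acc.append(100.0 * np.mean(pred == labels[test_idx]))
        y_true_all.extend(labels[test_idx])
        y_pred_all.extend(pred)
    confusion = _confusion(y_true_all, y_pred_all, order)
    mean_acc = 100.0 * np.trace(confusion) / confusion.sum()
    logger.info("crossvalidate_epochs: pooled accuracy %.2f%%", mean_acc)
    return ClassificationReport(fold_acc, float(mean_acc), confusion, order,
                                selected_features=selected)


def sweep_feature_count(features: FeatureMatrix | np.ndarray,
                        labels: np.ndarray | None = None,
                        config: DecoderConfig | None = None,
                        k_grid: tuple[int, ...] = tuple(range(5, 57, 5)),
                        inner_folds: int = 5,
                        ) -> tuple[int, dict]:
    """Nested CV over the selected-feature count.

    The inner loop scores each k on the outer-training split; the outer
    loop reports unbiased accuracy at the inner-selected k.  Returns the
    most frequently selected k (ties to the smaller k) and a summary dict
    with the mean inner accuracy curve and the outer accuracy.
    """
    config = config or DecoderConfig()
    if isinstance(features, FeatureMatrix):
        values = features.values
        labels = features.labels if labels is None else np.asarray(labels)
    else:
        values = np.asarray(features, float)
        labels = np.asarray(labels)
    y = labels.astype(str)
    if not all(1 <= k <= values.shape[1] for k in k_grid):
        raise ValueError(f"k_grid must lie within [1, {values.shape[1]}]")
    outer = StratifiedKFold(n_splits=config.folds, shuffle=True,
                            random_state=config.seed)
    curves, outer_acc, chosen_ks = [], [], []
    for train_idx, test_idx in outer.split(values, y):
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                                random_state=config.seed + 1)
        inner_scores = []
        for k in k_grid:
            accs = []
            for i_tr, i_te in inner.split(values[train_idx], y[train_idx]):
                pred, _ = _fit_predict(values[train_idx][i_tr],
                                       y[train_idx][i_tr],
                                       values[train_idx][i_te], config, k)
                accs.append(np.mean(pred == y[train_idx][i_te]))
            inner_scores.append(float(np.mean(accs)))
        curves.append(inner_scores)
        best_k = k_grid[int(np.argmax(inner_scores))]  # argmax -> smaller tie
        chosen_ks.append(best_k)
        pred, _ = _fit_predict(values[train_idx], y[train_idx],
                               values[test_idx], config, best_k)
        outer_acc.append(100.0 * np.mean(pred == y[test_idx]))
    ks, freq = np.unique(chosen_ks, return_counts=True)
    best_k = int(ks[np.argmax(freq)])
    summary = {
        "k_grid": list(k_grid),
        "inner_curve": list(np.mean(curves, axis=0) * 100.0),
        "outer_accuracy": float(np.mean(outer_acc)),
        "chosen_ks": chosen_ks,
    }
    return best_k, summary


# --------------------------------------------------------------------------
# online simulation
# --------------------------------------------------------------------------

def simulate_online(train: FeatureEpochSet, block7: FeatureEpochSet,
                    block8: FeatureEpochSet,
                    config: DecoderConfig | None = None,
                    ) -> tuple[ClassificationReport, ClassificationReport]:
    """Fit once on blocks 1-6, classify the two 40-trial feedback blocks.

    The spatial-filter bank is fitted on all four classes of the training
    blocks; each binary classifier (LL-vs-RR for block 7, LR-vs-RL for
    block 8) gets its own MI selection (k = ``config.k_features``) and SVM
    trained only on its two classes.  Test trials never enter any fitting
    step.
    """
    config = config or DecoderConfig()
    if train.n_trials == 0 or block7.n_trials == 0 or block8.n_trials == 0:
        raise ValueError("training and both feedback blocks are required")
    models = fit_spatial_models(train, n_dsp=config.n_dsp,
                                n_trca=config.n_trca, n_csp=config.n_csp,
                                shrinkage=config.shrinkage)
    f_train = extract_features(models, train)
    reports = []
    for pair, test_fe in ((("LL", "RR"), block7), (("LR", "RL"), block8)):
        rows = np.isin(f_train.labels.astype(str), pair)
        f_test = extract_features(models, test_fe)
        pred, chosen = _fit_predict(f_train.values[rows],
                                    f_train.labels[rows].astype(str),
                                    f_test.values, config, config.k_features)
        truth = f_test.labels.astype(str)
        confusion = _confusion(truth, pred, pair)
        acc = 100.0 * np.mean(pred == truth)
        decisions = pd.DataFrame({
            "trial": np.arange(len(truth)),
            "true": truth,
            "predicted": pred,
            "correct": pred == truth,
        })
        reports.append(ClassificationReport(
            [float(acc)], float(acc), confusion, pair,
            selected_features=[chosen], decisions=decisions))
    logger.info("simulate_online: LL-vs-RR %.2f%%, LR-vs-RL %.2f%%",
                reports[0].mean_accuracy, reports[1].mean_accuracy)
    return reports[0], reports[1]


# --------------------------------------------------------------------------
# behavioral timing
# --------------------------------------------------------------------------

def keystroke_interval_stats(events, rate: float) -> dict:
    """Per-task mean/SD of the key2 - key1 interval over well-formed trials,
    plus a one-way ANOVA across tasks (named in the output)."""
    per_task: dict[str, list[float]] = {}
    for trial in group_trials(events):
        keys = [e for e in trial.key_events
                if e.code in (EventCode.KEY_LEFT, EventCode.KEY_RIGHT)]
        if len(keys) != 2 or trial.task is None:
            continue
        per_task.setdefault(trial.task, []).append(
            (keys[1].sample - keys[0].sample) / rate)
    table = pd.DataFrame([
        {"task": t, "n": len(v), "mean_s": float(np.mean(v)),
         "sd_s": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
        for t, v in sorted(per_task.items())
    ])
    groups = [v for v in per_task.values() if len(v) > 1]
    anova = {"test": "one-way ANOVA", "statistic": np.nan, "p_value": np.nan}
    if len(groups) >= 2:
        f_stat, p = stats.f_oneway(*groups)
        anova.update(statistic=float(f_stat), p_value=float(p))
    pooled = np.concatenate([np.asarray(v) for v in per_task.values()])
    return {
        "per_task": table,
        "pooled_mean_s": float(pooled.mean()),
        "pooled_sd_s": float(pooled.std(ddof=1)),
        "across_task_test": anova,
    }
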