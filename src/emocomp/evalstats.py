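"""Statistical reproduction and classifier evaluation.

Two groups of utilities:

* reproduction of the published descriptive statistics on generated data
  — one-way ANOVA across the four emotion groups and per-class Pearson
  correlation tables (delegated to :mod:`scipy.stats`);
* classifier evaluation — multiclass confusion matrix/accuracy and
  one-vs-rest ROC AUC (midrank method, implemented here and cross-checked
  against exhaustive pair counting and scikit-learn in the tests), plus
  the two delegated comparator baselines: a Gaussian-kernel SVM (kernel
  scale 2.5, one-vs-rest) and a random-undersampling boosted tree
  ensemble (20 learners, at most 30 splits each).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from emocomp.datagen import EMOTIONS, STAT_FEATURES, records_to_frame
from emocomp.odcnn import TrainingReport


@dataclass
class AnovaResult:
    feature: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    f_stat: float
    p_value: float


def one_way_anova(groups: list[np.ndarray], feature: str = "") -> AnovaResult:
    """Classical one-way ANOVA F test across ≥ 2 groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least two groups with at least two members each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    f_stat, p = sps.f_oneway(*arrays)
    names = list(EMOTIONS[: len(arrays)])
    return AnovaResult(
        feature=feature,
        group_means={n: float(a.mean()) for n, a in zip(names, arrays)},
        group_sds={n: float(a.std(ddof=1)) for n, a in zip(names, arrays)},
        f_stat=float(f_stat), p_value=float(p))


def anova_table(records) -> pd.DataFrame:
    """ANOVA of each continuous feature across the four emotion groups."""
    df = records_to_frame(records)
    rows = []
    for feat in STAT_FEATURES:
        groups = [df.loc[df.emotion == e, feat].to_numpy() for e in EMOTIONS]
        res = one_way_anova(groups, feature=feat)
        rows.append({"feature": feat, "F": res.f_stat, "p": res.p_value})
    return pd.DataFrame(rows)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has undefined correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def correlation_table(records, emotion: str) -> pd.DataFrame:
    """All pairwise Pearson correlations of the continuous features in one class."""
    df = records_to_frame(records)
    sub = df[df.emotion == emotion]
    rows = []
    for i, a in enumerate(STAT_FEATURES):
        for b in STAT_FEATURES[i + 1:]:
            r, p = pearson_r(sub[a].to_numpy(), sub[b].to_numpy())
            rows.append({"emotion": emotion, "feature_a": a, "feature_b": b,
                         "r": r, "p": p})
    return pd.DataFrame(rows)


def confusion_and_accuracy(y_true: np.ndarray, y_pred: np.ndarray,
                           n_classes: int = 4) -> tuple[np.ndarray, float, int]:
    """Count matrix (rows = truth), overall accuracy, misclassified count."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if np.any((y_true < 0) | (y_true >= n_classes) |
              (y_pred < 0) | (y_pred >= n_classes)):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    correct = int(np.trace(conf))
    return conf, correct / len(y_true), len(y_true) - correct


def _binary_auc_midrank(scores: np.ndarray, positives: np.ndarray) -> float:
    """Mann–Whitney AUC via midranks; ties counted as half."""
    ranks = sps.rankdata(scores)  # midranks
    n_pos = int(positives.sum())
    n_neg = len(scores) - n_pos
    r_pos = ranks[positives].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc_ovr(y_true: np.ndarray, score_matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """One-vs-rest AUC per class and their unweighted macro mean.

    Classes absent from the truth vector get NaN and are excluded from
    the macro average.
    """
    y_true = np.asarray(y_true, dtype=int)
    S = np.asarray(score_matrix, dtype=float)
    if S.ndim != 2 or S.shape[0] != len(y_true):
        raise ValueError("score matrix must be (n, n_classes)")
    n_classes = S.shape[1]
    aucs = np.full(n_classes, np.nan)
    for c in range(n_classes):
        pos = y_true == c
        if pos.sum() == 0 or pos.sum() == len(y_true):
            continue
        aucs[c] = _binary_auc_midrank(S[:, c], pos)
    macro = float(np.nanmean(aucs))
    return aucs, macro


# ---------------------------------------------------------------------------
# comparator baselines (delegated implementations)
# ---------------------------------------------------------------------------

def _rus_boost(seed: int) -> AdaBoostClassifier:
    """RUSBoost-style ensemble: boosted depth-limited trees.

    Random undersampling to the minority-class size happens in
    :func:`run_comparators` before fitting (the boosting itself is
    scikit-learn AdaBoost over trees with at most 30 splits).
    """
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_leaf_nodes=31, random_state=seed),
        n_estimators=20, random_state=seed)


def _undersample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced random undersample of y."""
    counts = np.bincount(y)
    m = counts[counts > 0].min()
    keep = []
    for c in np.flatnonzero(counts):
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(keep))


def run_comparators(features: np.ndarray, labels: np.ndarray, k: int = 5,
                    seed: int = 0) -> dict[str, TrainingReport]:
    """Cross-validate the SVM and boosted-tree baselines on shared folds.

    Folds are generated exactly as in :func:`emocomp.odcnn.cross_validate`
    (StratifiedKFold, shuffle, random_state=seed), so reports are
    comparable with an ODCNN run using the same seed and k.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    out: dict[str, TrainingReport] = {}

    models = {
        # MATLAB-style "kernel scale" s corresponds to gamma = 1/s^2
        "svm": lambda s: OneVsRestClassifier(
            SVC(kernel="rbf", gamma=1.0 / 2.5**2, random_state=s)),
        "rusboost": _rus_boost,
    }
    for name, factory in models.items():
        pooled_true = np.empty(0, dtype=int)
        pooled_pred = np.empty(0, dtype=int)
        pooled_scores = np.empty((0, 4))
        for fold_i, (tr, te) in enumerate(folds):
            clf = factory(seed + fold_i)
            tr_used = tr
            if name == "rusboost":
                rng = np.random.default_rng(seed + fold_i)
                tr_used = tr[_undersample(y[tr], rng)]
            clf.fit(X[tr_used], y[tr_used])
            pred = clf.predict(X[te])
            if hasattr(clf, "decision_function"):
                sc = clf.decision_function(X[te])
            else:
                sc = clf.predict_proba(X[te])
            full = np.full((len(te), 4), -np.inf)
            present = clf.classes_ if hasattr(clf, "classes_") else np.arange(4)
            full[:, np.asarray(present, dtype=int)] = sc
            pooled_true = np.concatenate([pooled_true, y[te]])
            pooled_pred = np.concatenate([pooled_pred, pred])
            pooled_scores = np.vstack([pooled_scores, full])
        conf, acc, mis = confusion_and_accuracy(pooled_true, pooled_pred)
        per_class, macro = roc_auc_ovr(pooled_true, pooled_scores)
        out[name] = TrainingReport(accuracy=acc, confusion=conf, misclassified=mis,
                                   per_class_auc=per_class, macro_auc=macro,
                                   n=len(pooled_true))
    return out


def parallel_coordinates_data(features: np.ndarray, y_true: np.ndarray,
                              y_pred: np.ndarray) -> pd.DataFrame:
    """Standardized feature values plus a correctness flag, for external plotting."""
    from emocomp.datagen import FEATURE_COLUMNS

    X = np.asarray(features, dtype=float)
    df = pd.DataFrame(X, columns=list(FEATURE_COLUMNS)[: X.shape[1]])
    df["true_label"] = np.asarray(y_true, dtype=int)
    df["predicted_label"] = np.asarray(y_pred, dtype=int)
    df["correct"] = df.true_label == df.predicted_label
    return df
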