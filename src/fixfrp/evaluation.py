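"""ROC/AUC construction, cross-validation schemes, class contrasts and controls.

The ROC is built the way the classifier study defines it: real-valued decision
scores are min-max mapped onto [0, 1] and swept against K = 100 equally spaced
thresholds b_1 = 0 ... b_K = 1; the true-positive rate is expressed as a
function of the false-positive rate and the AUC is the trapezoidal area under
that curve.  Chance level is AUC = 0.5 regardless of the class prior.

Two schemes are provided: intra-subject stratified 10-fold cross-validation
(binary contrasts keep the true class priors; the 3-class case balances the
classes first and reports accuracy) and inter-subject leave-one-subject-out
generalization.  All of PCA, the shrinkage intensity and the discriminant are
fit on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import StratifiedKFold

from . import fda as _fda
from . import features as _features

CONTRASTS = (
    "target_vs_rest",
    "target_vs_nontarget",
    "target_vs_background",
    "nontarget_vs_background",
    "three_class",
)

#: positive / negative class composition per binary contrast
_BINARY_CONTRASTS = {
    "target_vs_rest": ({"target"}, {"nontarget", "background"}),
    "target_vs_nontarget": ({"target"}, {"nontarget"}),
    "target_vs_background": ({"target"}, {"background"}),
    "nontarget_vs_background": ({"nontarget"}, {"background"}),
}


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # K equally spaced in [0, 1]
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class CVResult:
    scheme: str
    contrast: str
    channel_set: str
    per_fold_metric: list[float]
    mean: float
    sd: float
    metric_name: str = "auc"
    extra: dict = field(default_factory=dict)


@dataclass
class SubjectData:
    """One subject's preprocessed epochs, ready for feature extraction."""

    epochs: list  # list of preprocess.Epoch
    subject_id: str = ""


def roc_auc(scores, labels, K: int = 100, pos_label=1) -> ROCCurve:
    """Threshold-sweep ROC with K equally spaced thresholds on min-max mapped
    scores, and trapezoidal AUC.

    The min-max mapping is monotone, so the AUC is unaffected by it; the
    mapping uses the evaluated score set's own min/max.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = labels == pos_label
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present to compute a ROC")
    lo, hi = scores.min(), scores.max()
    mapped = (scores - lo) / (hi - lo) if hi > lo else np.full_like(scores, 0.5)
    thresholds = np.linspace(0.0, 1.0, K)
    n_pos, n_neg = pos.sum(), (~pos).sum()
    tpr = np.empty(K)
    fpr = np.empty(K)
    for i, b in enumerate(thresholds):
        pred = mapped > b
        tpr[i] = np.sum(pred & pos) / n_pos
        fpr[i] = np.sum(pred & ~pos) / n_neg
    # sweep runs from (1,1) toward (0,0); close the curve at both ends
    fx = np.concatenate([[1.0], fpr, [0.0]])
    ty = np.concatenate([[1.0], tpr, [0.0]])
    auc = float(-np.trapezoid(ty, fx))  # fpr is decreasing, negate the integral
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def rank_auc(scores, labels, pos_label=1) -> float:
    """Exact rank-based (Mann-Whitney) AUC; the independent reference for the
    threshold-sweep construction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == pos_label]
    neg = scores[labels != pos_label]
    ranks = scipy.stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """k disjoint covering folds preserving class proportions (each fold's
    class counts within 1 sample of proportionality).  Returns test-index sets."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} samples, fewer than k={k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def balance_classes(labels, seed: int = 0) -> np.ndarray:
    """Seeded random down-sampling of the larger classes to the minimum class
    count; returns the retained indices in original order."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def make_contrast(labels, contrast: str) -> tuple[np.ndarray, np.ndarray]:
    """Select samples and binarize labels for a contrast.

    Returns (sample indices, y) with y in {0, 1} (1 = positive class) for
    binary contrasts, or the original string labels for 'three_class'.
    """
    labels = np.asarray(labels)
    if contrast == "three_class":
        return np.arange(len(labels)), labels
    if contrast not in _BINARY_CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    pos_set, neg_set = _BINARY_CONTRASTS[contrast]
    mask = np.isin(labels, list(pos_set | neg_set))
    idx = np.flatnonzero(mask)
    y = np.isin(labels[idx], list(pos_set)).astype(int)
    return idx, y


def _fit_and_score(
    X_train, y_train, X_test, y_test, pca_criterion: float, binary: bool
):
    """Train PCA + shrinkage-FDA on the training split only; return the test
    AUC (binary) or accuracy (multi-class)."""
    pca = _features.fit_pca(X_train, criterion=pca_criterion)
    Z_train = _features.project(pca, X_train)
    Z_test = _features.project(pca, X_test)
    model = _fda.fit_fda(Z_train, y_train)
    if binary:
        scores = _fda.decision_scores(model, Z_test)
        return roc_auc(scores, y_test, pos_label=1).auc, model
    pred = _fda.classify(model, Z_test)
    return float(np.mean(pred == np.asarray(y_test))), model


def run_intra_subject(
    dataset: SubjectData,
    contrast: str,
    channel_set: str = "eeg",
    seed: int = 0,
    k: int = 10,
    pca_criterion: float = 0.999,
    leak: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation within one subject.

    Binary contrasts keep the true class priors and report the AUC; the
    three-class case balances the classes before folding and reports accuracy.
    ``leak=True`` deliberately fits PCA and the discriminant on ALL data before
    scoring each fold — a negative control that must inflate null-data results.
    """
    X, labels = _features.epochs_to_matrix(dataset.epochs, channel_set)
    idx, y = make_contrast(labels, contrast)
    X = X[idx]
    binary = contrast != "three_class"
    if not binary:
        sel = balance_classes(y, seed=seed)
        X, y = X[sel], y[sel]
    folds = stratified_kfold(y, k=k, seed=seed)
    metrics = []
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        if leak:
            m, _ = _fit_and_score(X, y, X[test_idx], y[test_idx], pca_criterion, binary)
        else:
            m, _ = _fit_and_score(
                X[train_mask], y[train_mask], X[test_idx], y[test_idx], pca_criterion, binary
            )
        metrics.append(m)
    return CVResult(
        scheme="intra_subject_10fold",
        contrast=contrast,
        channel_set=channel_set,
        per_fold_metric=metrics,
        mean=float(np.mean(metrics)),
        sd=float(np.std(metrics, ddof=1)),
        metric_name="auc" if binary else "accuracy",
    )


def run_inter_subject(
    datasets: list[SubjectData],
    contrast: str,
    channel_set: str = "eeg",
    pca_criterion: float = 0.999,
) -> CVResult:
    """Leave-one-subject-out generalization: train on the pooled data of all
    other subjects, test on the held-out subject; AUC per held-out subject."""
    if len(datasets) < 2:
        raise ValueError("inter-subject evaluation needs at least 2 subjects")
    if contrast == "three_class":
        raise ValueError("inter-subject scheme evaluates binary contrasts only")
    mats = []
    for ds in datasets:
        X, labels = _features.epochs_to_matrix(ds.epochs, channel_set)
        idx, y = make_contrast(labels, contrast)
        mats.append((X[idx], y))
    metrics = []
    for held in range(len(datasets)):
        X_train = np.concatenate([m[0] for i, m in enumerate(mats) if i != held])
        y_train = np.concatenate([m[1] for i, m in enumerate(mats) if i != held])
        X_test, y_test = mats[held]
        m, _ = _fit_and_score(X_train, y_train, X_test, y_test, pca_criterion, binary=True)
        metrics.append(m)
    return CVResult(
        scheme="inter_subject_loso",
        contrast=contrast,
        channel_set=channel_set,
        per_fold_metric=metrics,
        mean=float(np.mean(metrics)),
        sd=float(np.std(metrics, ddof=1)) if len(metrics) > 1 else 0.0,
    )


def paired_ttest(metric_a, metric_b) -> tuple[float, float]:
    """Two-tailed paired t-test between matched metric samples (e.g. the same
    subjects under two conditions).  Zero within-pair variance is handled
    explicitly: identical samples give (0, 1); a constant nonzero difference
    gives (+/-inf, 0)."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        if diff.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), float(p)


def export_fda_projection(model, X, labels) -> pd.DataFrame:
    """Per-sample coordinates on the two leading FDA axes of a 3-class model,
    as a table for external plotting."""
    if model.n_classes < 3 or model.projection.shape[1] < 2:
        raise ValueError("2-D projection export requires a (>=) 3-class model")
    Z = (np.asarray(X, dtype=float) - model.global_mean) @ model.projection[:, :2]
    return pd.DataFrame({"dim1": Z[:, 0], "dim2": Z[:, 1], "label": np.asarray(labels)})
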