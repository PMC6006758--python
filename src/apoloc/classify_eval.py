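"""RBF-SVM one-vs-one classification, jackknife evaluation, and metrics.

Hyperparameters come from an exhaustive power-of-two grid (C in 2^-5..2^15,
gamma in 2^-15..2^5, integer exponents) scored by seeded stratified K-fold
accuracy; ties go to the smaller C, then the smaller gamma.  Evaluation is
leave-one-out: the prediction for each held-out sample is the majority vote
over the pairwise classifiers with ties resolved to the smallest class index,
and the reported scores are pairwise-coupled class probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass
class SvmConfig:
    """Grid bounds (integer log2 exponents) and cross-validation settings."""

    c_exponents: Sequence[int] = field(
        default_factory=lambda: list(range(-5, 16)))
    gamma_exponents: Sequence[int] = field(
        default_factory=lambda: list(range(-15, 6)))
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(-5 <= e <= 15 for e in self.c_exponents):
            raise ValueError("C exponents must lie in [-5, 15]")
        if not all(-15 <= e <= 5 for e in self.gamma_exponents):
            raise ValueError("gamma exponents must lie in [-15, 5]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class JackknifeResult:
    """Leave-one-out predictions with class-membership scores."""

    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # n x c, columns aligned with `classes`
    classes: np.ndarray

    def __post_init__(self) -> None:
        n = self.y_true.size
        if self.y_pred.size != n or self.scores.shape[0] != n:
            raise ValueError("inconsistent result sizes")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite score rows")


@dataclass
class EvalReport:
    """Per-class sensitivity/specificity/MCC, overall accuracy, macro AUC."""

    classes: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    mcc: np.ndarray
    overall_accuracy: float
    confusion: np.ndarray
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "classes": self.classes.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "mcc": self.mcc.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
        }

    def format_text(self) -> str:
        lines = ["class  Sens    Spec    MCC"]
        for i, c in enumerate(self.classes):
            lines.append(
                f"{c!s:>5}  {self.sensitivity[i]:.4f}  "
                f"{self.specificity[i]:.4f}  {self.mcc[i]:+.4f}"
            )
        lines.append(f"OA = {self.overall_accuracy:.4f}")
        if self.auc is not None:
            lines.append(f"macro AUC = {self.auc:.4f}")
        return "\n".join(lines)


def grid_search_rbf(
    X: np.ndarray, y: np.ndarray, cfg: SvmConfig
) -> tuple[float, float, pd.DataFrame]:
    """Exhaustive (C, gamma) search by seeded stratified K-fold accuracy.

    Returns the winning pair plus the full score table; ties break toward
    smaller C, then smaller gamma.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("grid search needs at least two classes")
    if counts.min() < cfg.cv_folds:
        raise ValueError(
            f"every class needs >= cv_folds={cfg.cv_folds} members for "
            f"stratified folds; smallest class has {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                          random_state=cfg.seed)
    splits = list(skf.split(X, y))

    rows = []
    best = None  # (-accuracy, C, gamma) — lexicographic min implements ties
    for ce in sorted(cfg.c_exponents):
        C = 2.0 ** ce
        for ge in sorted(cfg.gamma_exponents):
            gamma = 2.0 ** ge
            correct = 0
            for train_idx, test_idx in splits:
                clf = SVC(kernel="rbf", C=C, gamma=gamma)
                clf.fit(X[train_idx], y[train_idx])
                correct += int(np.sum(clf.predict(X[test_idx]) == y[test_idx]))
            acc = correct / y.size
            rows.append({"C": C, "gamma": gamma, "cv_accuracy": acc})
            key = (-acc, C, gamma)
            if best is None or key < best:
                best = key
    table = pd.DataFrame(rows)
    _, C_star, gamma_star = best
    return C_star, gamma_star, table


def ovo_vote_tiebreak(votes: Sequence[float]) -> int:
    """Index of the most-voted class; ties resolve to the smallest index."""
    votes = np.asarray(votes)
    return int(np.argmax(votes))  # argmax returns the first maximum


def _votes_from_ovo_decision(
    decision: np.ndarray, n_classes: int
) -> np.ndarray:
    """Vote counts from a one-vs-one decision row ordered (0,1),(0,2),..."""
    votes = np.zeros(n_classes)
    k = 0
    for a in range(n_classes):
        for b in range(a + 1, n_classes):
            if decision[k] > 0:
                votes[a] += 1
            else:
                votes[b] += 1
            k += 1
    return votes


def _fit_fold(
    X: np.ndarray,
    y: np.ndarray,
    test_index: int,
    C: float,
    gamma: float,
    seed: int,
    reducer: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]] | None = None,
):
    """Train one leave-one-out fold; returns (classifier, transform callable)."""
    mask = np.ones(y.size, dtype=bool)
    mask[test_index] = False
    X_train, y_train = X[mask], y[mask]
    if reducer is not None:
        transform = reducer(X_train, y_train)
    else:
        transform = lambda Z: Z
    # Pairwise-coupled Platt probabilities; scheduled for removal from SVC
    # but still the coupling estimator wanted here, so mute the notice.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        clf = SVC(kernel="rbf", C=C, gamma=gamma, probability=True,
                  decision_function_shape="ovo", random_state=seed)
        clf.fit(transform(X_train), y_train)
    return clf, transform


def jackknife_predict(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    seed: int = 0,
    reducer: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]] | None = None,
) -> JackknifeResult:
    """Leave-one-out evaluation with fixed hyperparameters.

    ``reducer``, when given, is fit on each fold's n-1 training rows and
    returns the transform applied to both the training rows and the held-out
    row — the strict, leakage-free protocol.  With ``reducer=None`` the rows
    of X are used as-is (the as-published protocol when X was reduced on the
    full dataset beforehand).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = y.size
    if n < 2:
        raise ValueError("jackknife needs at least two samples")
    classes = np.unique(y)
    c = classes.size
    y_pred = np.empty(n, dtype=y.dtype)
    scores = np.empty((n, c))
    class_pos = {cl: i for i, cl in enumerate(classes)}
    for i in range(n):
        try:
            clf, transform = _fit_fold(X, y, i, C, gamma, seed, reducer)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"jackknife fold {i} failed: {exc}") from exc
        x_test = transform(X[i : i + 1])
        fold_classes = clf.classes_
        if fold_classes.size == c and c > 2:
            decision = np.atleast_2d(clf.decision_function(x_test))[0]
            votes = _votes_from_ovo_decision(decision, c)
            y_pred[i] = classes[ovo_vote_tiebreak(votes)]
        elif fold_classes.size == 2:
            # binary decision_function is sign-flipped relative to the
            # pairwise columns: positive means the second class
            decision = float(np.ravel(clf.decision_function(x_test))[0])
            y_pred[i] = fold_classes[1] if decision > 0 else fold_classes[0]
        else:  # a class vanished from the training fold (singleton class)
            y_pred[i] = clf.predict(x_test)[0]
        proba = clf.predict_proba(x_test)[0]
        row = np.zeros(c)
        for cl, p in zip(fold_classes, proba):
            row[class_pos[cl]] = p
        scores[i] = row
    return JackknifeResult(y_true=y.copy(), y_pred=y_pred, scores=scores,
                           classes=classes)


def _binary_mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def binary_counts_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Sens/Spec/MCC/OA straight from a binary confusion; 0/0 ratios -> 0."""
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    oa = (tp + tn) / (tp + tn + fp + fn)
    return {"sens": sens, "spec": spec, "mcc": _binary_mcc(tp, tn, fp, fn),
            "oa": oa}


def per_class_metrics(result: JackknifeResult) -> EvalReport:
    """One-vs-rest Sens/Spec/MCC per class plus multiclass overall accuracy."""
    y_true, y_pred = result.y_true, result.y_pred
    classes = result.classes
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    n = y_true.size
    sens = np.empty(classes.size)
    spec = np.empty(classes.size)
    mcc = np.empty(classes.size)
    for i in range(classes.size):
        tp = int(cm[i, i])
        fn = int(cm[i].sum() - tp)
        fp = int(cm[:, i].sum() - tp)
        tn = n - tp - fn - fp
        m = binary_counts_metrics(tp, tn, fp, fn)
        sens[i], spec[i], mcc[i] = m["sens"], m["spec"], m["mcc"]
    oa = float(np.trace(cm)) / n
    return EvalReport(classes=classes, sensitivity=sens, specificity=spec,
                      mcc=mcc, overall_accuracy=oa, confusion=cm)


def ovr_roc_auc(
    result: JackknifeResult, grid_points: int = 101
) -> tuple[float, dict, pd.DataFrame]:
    """Macro ROC by one-vs-rest binarization.

    Per-class TPR curves are interpolated onto a shared FPR grid and
    averaged; the macro AUC is the trapezoid area under the averaged curve.
    Classes absent from y_true are skipped with a warning.
    """
    fpr_grid = np.linspace(0.0, 1.0, grid_points)
    mean_tpr = np.zeros_like(fpr_grid)
    per_class: dict = {}
    used = 0
    for i, cl in enumerate(result.classes):
        positives = result.y_true == cl
        if not positives.any():
            logger.warning("class %r absent from y_true; skipped in ROC", cl)
            continue
        fpr, tpr, _ = roc_curve(positives.astype(int), result.scores[:, i])
        per_class[cl] = float(np.trapezoid(tpr, fpr))
        mean_tpr += np.interp(fpr_grid, fpr, tpr)
        used += 1
    if used == 0:
        raise ValueError("no class present in y_true")
    mean_tpr /= used
    mean_tpr[0] = 0.0
    macro_auc = float(np.trapezoid(mean_tpr, fpr_grid))
    curve = pd.DataFrame({"fpr": fpr_grid, "mean_tpr": mean_tpr})
    return macro_auc, per_class, curve
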