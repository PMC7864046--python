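"""Per-class F-measure evaluation under stratified cross-validation.

The F-measure of class i is the harmonic mean of its precision
P_i = n_ii / sum_j n_ji and recall R_i = n_ii / sum_j n_ij, where
n_ij counts samples of actual class i predicted as class j.  Classifier
performance is summarized by FM_all (mean over classes) and FM_min
(worst class).  Confusion matrices are summed over folds before
per-class F-measures are computed, which is numerically stable when
folds are small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import make_classifier
from .features import FeatureTable

__all__ = [
    "confusion_matrix",
    "f_measure",
    "stratified_folds",
    "evaluate_subset",
    "sensor_combination_sweep",
    "EvaluationResult",
    "STUDY_COMBINATIONS",
]

#: the seven sensor combinations examined in lower-limb HAR studies,
#: expressed as modality filters over feature provenance
STUDY_COMBINATIONS: dict[str, tuple[str, ...]] = {
    "sEMG": ("emg",),
    "ACC": ("acc",),
    "GYR": ("gyr",),
    "Joint Ang.": ("angle",),
    "IMU": ("acc", "gyr"),
    "sEMG+IMU": ("emg", "acc", "gyr"),
    "sEMG+IMU+Joint Ang.": ("emg", "acc", "gyr", "angle"),
}


@dataclass
class EvaluationResult:
    classifier: str
    per_class_fm: dict[str, float]
    fm_all: float
    fm_min: float
    per_class_precision: dict[str, float] = field(default_factory=dict)
    per_class_recall: dict[str, float] = field(default_factory=dict)
    n_features: int = 0
    flags: list[str] = field(default_factory=list)


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Counts n_ij (row = actual, column = predicted); returns (cm, classes)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm, classes


def f_measure(cm: np.ndarray) -> tuple[np.ndarray, float, float, np.ndarray, np.ndarray]:
    """Per-class FM, FM_all, FM_min, precision and recall from a confusion
    matrix.  Zero denominators yield 0 by convention."""
    cm = np.asarray(cm, dtype=float)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        denom = precision + recall
        fm = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return fm, float(fm.mean()), float(fm.min()), precision, recall


def stratified_folds(
    y: np.ndarray, n_folds: int, seed: int = 0
) -> list[np.ndarray]:
    """Deterministic stratified fold assignment: class members are
    shuffled and dealt round-robin, so folds are as balanced as the
    class sizes allow."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for c in np.unique(y):
        members = np.nonzero(y == c)[0]
        rng.shuffle(members)
        for i, idx in enumerate(members):
            folds[(i + offset) % n_folds].append(int(idx))
        offset += len(members)
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validated_fm(
    X: np.ndarray,
    y: np.ndarray,
    classifier,
    folds: list[np.ndarray],
    classes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Confusion matrix summed over CV folds for one classifier."""
    if classes is None:
        classes = np.unique(y)
    total = np.zeros((len(classes), len(classes)), dtype=int)
    all_idx = np.arange(len(y))
    for test_idx in folds:
        if len(test_idx) == 0:
            continue
        train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=False)
        model = classifier.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        cm, _ = confusion_matrix(y[test_idx], pred, classes)
        total += cm
    return total, classes


def evaluate_subset(
    table: FeatureTable,
    subset: list[str] | None,
    classifier: str,
    n_folds: int = 10,
    seed: int = 0,
) -> EvaluationResult:
    """Stratified k-fold evaluation of a feature subset with one of the
    six study classifiers."""
    names = list(subset) if subset is not None else table.feature_names
    if not names:
        raise ValueError("empty feature subset")
    X = table.X[names].to_numpy(dtype=float)
    y = np.asarray(table.labels)
    folds = stratified_folds(y, n_folds, seed)
    clf = make_classifier(classifier, seed=seed)
    cm, classes = cross_validated_fm(X, y, clf, folds)
    fm, fm_all, fm_min, prec, rec = f_measure(cm)
    return EvaluationResult(
        classifier=classifier,
        per_class_fm={str(c): float(v) for c, v in zip(classes, fm)},
        fm_all=fm_all,
        fm_min=fm_min,
        per_class_precision={str(c): float(v) for c, v in zip(classes, prec)},
        per_class_recall={str(c): float(v) for c, v in zip(classes, rec)},
        n_features=len(names),
    )


def combination_features(
    table: FeatureTable, modalities: tuple[str, ...]
) -> list[str]:
    """Feature names whose provenance modality is in ``modalities``."""
    out = []
    for name in table.feature_names:
        d = table.provenance.get(name)
        if d is None:
            raise ValueError(f"feature {name!r} has no modality provenance")
        if d.modality in modalities:
            out.append(name)
    return out


def sensor_combination_sweep(
    table: FeatureTable,
    classifiers: list[str],
    combinations: dict[str, tuple[str, ...]] | None = None,
    selectors: dict[str, callable] | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Selector x classifier grid over sensor combinations.

    ``selectors`` maps a selector name to a callable taking the
    combination's FeatureTable and returning the selected feature
    names; the default runs every classifier on all features.  Returns
    a tidy frame with columns (combination, selector, classifier, FN,
    FM, FM_min) — the familiar results-table shape.
    """
    combos = combinations or STUDY_COMBINATIONS
    sels = selectors or {"All Features": lambda t: t.feature_names}
    rows = []
    for combo_name, modalities in combos.items():
        unknown = set(modalities) - {"emg", "acc", "gyr", "angle"}
        if unknown:
            raise ValueError(f"unknown modality in combination: {sorted(unknown)}")
        names = combination_features(table, modalities)
        if not names:
            continue
        sub = table.subset(names)
        for sel_name, sel in sels.items():
            chosen = list(sel(sub))
            for clf in classifiers:
                res = evaluate_subset(sub, chosen, clf, n_folds=n_folds, seed=seed)
                rows.append(
                    {
                        "combination": combo_name,
                        "selector": sel_name,
                        "classifier": clf,
                        "FN": len(chosen),
                        "FM": res.fm_all,
                        "FM_min": res.fm_min,
                    }
                )
    return pd.DataFrame(rows)
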