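"""Randomized stratified k-fold with probability averaging, and reporting.

The cross-validation repeats a stratified K-fold split many times; on
each repetition every sample lands in the test fold exactly once, and
its class probabilities are accumulated. The averaged probabilities are
the classifier's per-sample confidence, from which confusion matrices,
sensitivity/specificity/accuracy and per-compound summaries are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold


@dataclass
class CvResult:
    """Averaged cross-validated probabilities.

    p_avg: (n_samples, n_classes); counts[i] equals n_kfold (each sample
    is tested exactly once per repetition).
    """

    p_avg: np.ndarray
    counts: np.ndarray
    classes: np.ndarray
    n_fold: int
    n_kfold: int
    seed: int

    @property
    def predicted(self) -> np.ndarray:
        """Argmax of averaged probabilities (ties: first class)."""
        return self.classes[np.argmax(self.p_avg, axis=1)]

    @property
    def confidence(self) -> np.ndarray:
        """Averaged probability of the predicted class."""
        return np.max(self.p_avg, axis=1)


def randomized_kfold(M, l, n_fold: int = 2, n_kfold: int = 500,
                     classifier=None, seed: int = 0) -> CvResult:
    """Repeat stratified ``n_fold``-fold splitting ``n_kfold`` times.

    Each repetition trains the classifier on the fold complement and
    accumulates test-fold class probabilities; per-sample averages are
    returned. Reproducible under ``seed``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    l = np.asarray(l)
    classes, counts_per_class = np.unique(l, return_counts=True)
    if counts_per_class.min() < n_fold:
        raise ValueError(
            f"every class needs at least n_fold={n_fold} samples; "
            f"smallest class has {counts_per_class.min()}")
    base = classifier if classifier is not None else LinearDiscriminantAnalysis()
    p_sum = np.zeros((M.shape[0], classes.size))
    counts = np.zeros(M.shape[0], dtype=int)
    rng = np.random.default_rng(seed)
    for _ in range(n_kfold):
        skf = StratifiedKFold(n_splits=n_fold, shuffle=True,
                              random_state=int(rng.integers(0, 2 ** 31 - 1)))
        for train_idx, test_idx in skf.split(M, l):
            clf = clone(base)
            clf.fit(M[train_idx], l[train_idx])
            proba = clf.predict_proba(M[test_idx])
            # align to the global class order
            col = {c: j for j, c in enumerate(clf.classes_)}
            for j, c in enumerate(classes):
                if c in col:
                    p_sum[test_idx, j] += proba[:, col[c]]
            counts[test_idx] += 1
    p_avg = p_sum / counts[:, None]
    return CvResult(p_avg=p_avg, counts=counts, classes=classes,
                    n_fold=n_fold, n_kfold=n_kfold, seed=seed)


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame
    accuracy: float
    sensitivity: float | None = None   # binary only, w.r.t. positive class
    specificity: float | None = None
    per_compound: pd.DataFrame | None = None


def confusion_and_metrics(y_true, y_pred, positive=None) -> ClassificationReport:
    """Confusion counts plus sensitivity/specificity/accuracy.

    For binary problems ``positive`` names the risk/blocker class
    (defaults to the lexicographically last class). Raises on predicted
    labels never seen in the true labels.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    classes = np.unique(y_true)
    if not set(np.unique(y_pred)) <= set(classes):
        raise ValueError("prediction contains unseen label")
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    acc = float(np.trace(cm.values) / cm.values.sum())
    sens = spec = None
    if classes.size == 2:
        pos = positive if positive is not None else classes[-1]
        neg = [c for c in classes if c != pos][0]
        tp = cm.loc[pos, pos]
        fn = cm.loc[pos, neg]
        tn = cm.loc[neg, neg]
        fp = cm.loc[neg, pos]
        sens = float(tp / (tp + fn)) if tp + fn else float("nan")
        spec = float(tn / (tn + fp)) if tn + fp else float("nan")
    return ClassificationReport(confusion=cm, accuracy=acc,
                                sensitivity=sens, specificity=spec)


def aggregate_by_compound(provenance: pd.DataFrame, y_true, y_pred,
                          confidence, by_concentration: bool = False,
                          proba: np.ndarray | None = None,
                          classes=None) -> pd.DataFrame:
    """Per-compound (optionally per-concentration) classification summary.

    Reports the proportion of replicates classified to the labelled
    class and the mean confidence among correctly and incorrectly
    classified replicates (absent, not zero, when a group is empty).
    With ``proba`` given, also reports the mean class-probability
    vector (ternary-style aggregation).
    """
    df = provenance.copy().reset_index(drop=True)
    df["_true"] = np.asarray(y_true)
    df["_pred"] = np.asarray(y_pred)
    df["_conf"] = np.asarray(confidence, dtype=float)
    df["_ok"] = df["_true"] == df["_pred"]
    keys = ["compound"] + (["concentration"] if by_concentration else [])
    out = []
    for key, grp in df.groupby(keys, dropna=False, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        rec["n"] = len(grp)
        if len(grp) == 0:
            out.append(rec)
            continue
        rec["proportion_correct"] = float(grp["_ok"].mean())
        ok = grp.loc[grp["_ok"], "_conf"]
        bad = grp.loc[~grp["_ok"], "_conf"]
        rec["confidence_correct"] = float(ok.mean()) if len(ok) else None
        rec["confidence_incorrect"] = float(bad.mean()) if len(bad) else None
        if proba is not None and classes is not None:
            mean_p = np.asarray(proba)[grp.index].mean(axis=0)
            for c, p in zip(classes, mean_p):
                rec[f"p_{c}"] = float(p)
        out.append(rec)
    return pd.DataFrame(out)
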