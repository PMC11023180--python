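"""Baseline construction and statistical validation of the classifier.

Implements the majority-class baseline and the 5x2cv paired t-test
(Dietterich 1998): five replications of 2-fold cross-validation, the
statistic is the first fold difference of the first replication divided by
the root mean of the five per-replication variances, referred to a t
distribution with 5 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold, KFold

__all__ = [
    "majority_baseline",
    "cv52_ttest",
    "t_from_fold_differences",
    "accuracy_distribution",
    "CvTestResult",
]


def majority_baseline() -> DummyClassifier:
    """Classifier predicting the majority training class for every sample.

    With a 50/50 training set the tie resolves to class 0 (the first class
    in sorted label order).
    """
    return DummyClassifier(strategy="most_frequent")


@dataclass
class CvTestResult:
    """Outcome of the 5x2cv paired t-test."""

    t_statistic: float
    p_value: float
    fold_differences: np.ndarray  # 5 x 2 accuracy differences (a minus b)
    df: int = 5

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def cv52_ttest(
    X,
    y,
    model_a,
    model_b,
    seed: int = 0,
    stratified: bool = True,
) -> CvTestResult:
    """5x2cv paired t-test comparing two classifiers.

    Five replications of 2-fold cross-validation; in each fold the accuracy
    difference d = acc(a) − acc(b) is recorded. With per-replication mean
    d̄_i and variance s_i² = (d_i1 − d̄_i)² + (d_i2 − d̄_i)², the statistic is

        t = d_11 / sqrt(mean_i s_i²)

    and the two-sided p-value comes from a t distribution with 5 df.
    Folds are stratified by class by default (avoids single-class folds at
    small n). Degenerate cases: all ten differences zero → t = 0, p = 1;
    zero variance with a nonzero d_11 → p = 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    for label, count in zip(*np.unique(y, return_counts=True)):
        if count < 2:
            raise ValueError(f"need >= 2 samples per class (class {label}: {count})")
    diffs = np.zeros((5, 2))
    for rep in range(5):
        splitter_cls = StratifiedKFold if stratified else KFold
        splitter = splitter_cls(n_splits=2, shuffle=True, random_state=seed + rep)
        for fold, (train, test) in enumerate(splitter.split(X, y)):
            a = clone(model_a).fit(X[train], y[train])
            b = clone(model_b).fit(X[train], y[train])
            acc_a = accuracy_score(y[test], a.predict(X[test]))
            acc_b = accuracy_score(y[test], b.predict(X[test]))
            diffs[rep, fold] = acc_a - acc_b
    return t_from_fold_differences(diffs)


def t_from_fold_differences(diffs: np.ndarray) -> CvTestResult:
    """Assemble the 5x2cv statistic from a 5x2 fold-difference matrix."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.shape != (5, 2):
        raise ValueError("expected a 5x2 matrix of fold differences")
    rep_means = diffs.mean(axis=1, keepdims=True)
    s2 = ((diffs - rep_means) ** 2).sum(axis=1)
    denom = np.sqrt(s2.mean())
    d11 = diffs[0, 0]
    if denom == 0.0:
        if d11 == 0.0:
            return CvTestResult(t_statistic=0.0, p_value=1.0, fold_differences=diffs)
        warnings.warn("zero variance across folds with a nonzero difference")
        return CvTestResult(
            t_statistic=float(np.inf if d11 > 0 else -np.inf),
            p_value=0.0,
            fold_differences=diffs,
        )
    t = float(d11 / denom)
    p = float(2.0 * stats.t.sf(abs(t), df=5))
    return CvTestResult(t_statistic=t, p_value=p, fold_differences=diffs)


def accuracy_distribution(fits) -> dict[str, float]:
    """Summarise held-out accuracies over resampled fits.

    Accepts FitRecords or raw floats; returns mean, min, quartiles, max —
    the numbers behind an accuracy-range boxplot.
    """
    accs = np.array(
        [f.accuracy if hasattr(f, "accuracy") else float(f) for f in fits]
    )
    if accs.size == 0:
        raise ValueError("need at least one fit")
    q25, q50, q75 = np.percentile(accs, [25, 50, 75])
    return {
        "mean": float(accs.mean()),
        "min": float(accs.min()),
        "q25": float(q25),
        "median": float(q50),
        "q75": float(q75),
        "max": float(accs.max()),
        "n": int(accs.size),
    }
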