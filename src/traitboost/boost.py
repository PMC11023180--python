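"""Resampled gradient-boosting variant selection.

The selection statistic is the *appearance frequency*: a gradient-boosted
binary classifier is tuned once per trait, refit on many resampled 80/20
training splits, and each variant is scored by the number of fits in which
it received a gain importance (i.e. was used in at least one tree split).
Variants appearing in strictly more than ``threshold`` fits are selected.

Missing dosages are passed to the tree learner as NaN; XGBoost routes them
through its learned default split directions, so no imputation happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted, validate_data

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitRecord",
    "SelectionResult",
    "tune",
    "resample_fit",
    "select_variants",
    "ResampledBoostSelector",
]

#: Random/TPE-style search space: conventional ranges bracketing the
#: library defaults for the six tuned hyperparameters.
TUNING_RANGES = {
    "learning_rate": ("log", 0.01, 0.3),
    "max_depth": ("int", 2, 10),
    "min_child_weight": ("uniform", 1.0, 10.0),
    "gamma": ("uniform", 0.0, 5.0),
    "subsample": ("uniform", 0.5, 1.0),
    "colsample_bytree": ("uniform", 0.5, 1.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the boosted classifier.

    Defaults are conservatively regularised for the p >> n genotype setting
    (shallow trees, shrinkage, row/column subsampling); the boosting-round
    count is fixed rather than tuned.
    """

    learning_rate: float = 0.1
    max_depth: int = 3
    min_child_weight: float = 5.0
    gamma: float = 1.0
    subsample: float = 0.8
    colsample_bytree: float = 0.8
    n_estimators: int = 100
    objective: str = "binary:logistic"

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        for name in ("subsample", "colsample_bytree"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")

    def make_classifier(self, random_state: int = 0) -> xgb.XGBClassifier:
        return xgb.XGBClassifier(
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            min_child_weight=self.min_child_weight,
            gamma=self.gamma,
            subsample=self.subsample,
            colsample_bytree=self.colsample_bytree,
            n_estimators=self.n_estimators,
            objective=self.objective,
            tree_method="hist",
            n_jobs=1,
            verbosity=0,
            random_state=random_state,
        )


@dataclass
class FitRecord:
    """One resampled fit: split seed, held-out accuracy, per-variant gains."""

    seed: int
    accuracy: float
    gain_scores: dict[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class SelectionResult:
    """Appearance counts, summed gains and selected flags per variant."""

    table: pd.DataFrame  # variant_id, appearance_count, total_gain, selected
    threshold: int
    n_fits: int

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "variant_id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _sample_spec(rng: np.random.Generator, n_estimators: int) -> ModelSpec:
    draw = {}
    for name, (kind, lo, hi) in TUNING_RANGES.items():
        if kind == "log":
            draw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "int":
            draw[name] = int(rng.integers(lo, hi + 1))
        else:
            draw[name] = float(rng.uniform(lo, hi))
    return ModelSpec(n_estimators=n_estimators, **draw)


def _check_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("trait must have both classes present")
    if len(classes) > 2 or not set(classes) <= {0, 1}:
        raise ValueError("trait labels must be binary 0/1")
    return X, y.astype(int)


def tune(
    X,
    y,
    budget: int = 100,
    seed: int = 0,
    n_estimators: int = 100,
    test_size: float = 0.2,
) -> ModelSpec:
    """Seeded random search over the six-hyperparameter space.

    Each candidate is scored by held-out accuracy on one fixed 80/20 split
    (the split depends only on ``seed``); the best candidate is returned.
    Deterministic for a fixed seed. The first candidate is the package
    default spec so a budget of 1 returns it.
    """
    if budget < 1:
        raise ValueError("tuning budget must be >= 1")
    X, y = _check_xy(X, y)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed
    )
    if len(np.unique(y_tr)) < 2:
        raise ValueError("tuning split left a single-class training set")
    rng = np.random.default_rng(seed)
    best_spec, best_acc = None, -1.0
    for i in range(budget):
        spec = (
            ModelSpec(n_estimators=n_estimators)
            if i == 0
            else _sample_spec(rng, n_estimators)
        )
        clf = spec.make_classifier(random_state=seed)
        clf.fit(X_tr, y_tr)
        acc = accuracy_score(y_te, clf.predict(X_te))
        if acc > best_acc:
            best_spec, best_acc = spec, acc
    return best_spec


def resample_fit(
    X,
    y,
    spec: ModelSpec | None = None,
    n_fits: int = 100,
    base_seed: int = 0,
    feature_names: Sequence[str] | None = None,
    test_size: float = 0.2,
    stratify: bool = False,
) -> list[FitRecord]:
    """Refit the frozen spec on ``n_fits`` resampled 80/20 splits.

    Each fit records the held-out accuracy and the gain-importance map of
    the fitted booster (variants absent from the map were used in no
    split). Splits are unstratified by default; a split whose training set
    contains a single class is redrawn with the next seed (logged).
    """
    if n_fits < 1:
        raise ValueError("n_fits must be >= 1")
    X, y = _check_xy(X, y)
    spec = spec or ModelSpec()
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"f{i}" for i in range(X.shape[1])]
    )
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length must match number of columns")
    records: list[FitRecord] = []
    seed = base_seed
    while len(records) < n_fits:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X,
            y,
            test_size=test_size,
            random_state=seed,
            stratify=y if stratify else None,
        )
        if len(np.unique(y_tr)) < 2:
            logger.info("split seed %d produced a single-class training set; redrawn", seed)
            seed += 1
            continue
        clf = spec.make_classifier(random_state=seed)
        clf.fit(X_tr, y_tr)
        acc = accuracy_score(y_te, clf.predict(X_te))
        raw = clf.get_booster().get_score(importance_type="gain")
        gains = {names[int(k[1:])]: float(v) for k, v in raw.items()}
        records.append(FitRecord(seed=seed, accuracy=acc, gain_scores=gains))
        seed += 1
    return records


def select_variants(
    fits: Sequence[FitRecord],
    threshold: int = 20,
    variant_ids: Sequence[str] | None = None,
) -> SelectionResult:
    """Count appearances across fits and flag variants above the threshold.

    ``appearance_count`` is the number of fits whose gain map contains the
    variant; a variant is selected iff its count is *strictly* greater than
    ``threshold`` (with the defaults: appearing 21 of 100 times selects,
    appearing exactly 20 does not).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("empty fit list")
    if threshold >= len(fits):
        raise ValueError("threshold must be smaller than the number of fits")
    counts: dict[str, int] = {}
    gains: dict[str, float] = {}
    for record in fits:
        for vid, gain in record.gain_scores.items():
            counts[vid] = counts.get(vid, 0) + 1
            gains[vid] = gains.get(vid, 0.0) + gain
    ids = list(variant_ids) if variant_ids is not None else sorted(counts)
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "appearance_count": [counts.get(v, 0) for v in ids],
            "total_gain": [gains.get(v, 0.0) for v in ids],
        }
    )
    table["selected"] = table["appearance_count"] > threshold
    return SelectionResult(table=table, threshold=threshold, n_fits=len(fits))


class ResampledBoostSelector(SelectorMixin, BaseEstimator):
    """Feature selector based on resampled boosted-tree appearance frequency.

    ``fit(X, y)`` optionally tunes the classifier on one split, refits it on
    ``n_fits`` resampled 80/20 splits, and selects the features whose gain
    importance appears in strictly more than ``threshold`` fits.

    Parameters
    ----------
    model_spec : ModelSpec or None
        Frozen hyperparameters. If None and ``tune_budget > 0`` the spec is
        tuned by seeded random search; if None and ``tune_budget == 0`` the
        package default spec is used.
    n_fits, threshold : int
        Resampling depth and strict appearance-count threshold.
    tune_budget : int
        Number of random-search evaluations (0 disables tuning).
    random_state : int
        Base seed for tuning and for the sequence of resampling splits.

    Attributes
    ----------
    model_spec_ : ModelSpec
        The spec actually used for the resampled fits.
    fit_records_ : list of FitRecord
    selection_ : SelectionResult
    appearance_counts_ : ndarray of int, one per input feature
    support_ : boolean mask of selected features
    """

    def __init__(
        self,
        model_spec: ModelSpec | None = None,
        n_fits: int = 100,
        threshold: int = 20,
        tune_budget: int = 0,
        random_state: int = 0,
        feature_names: Sequence[str] | None = None,
    ):
        self.model_spec = model_spec
        self.n_fits = n_fits
        self.threshold = threshold
        self.tune_budget = tune_budget
        self.random_state = random_state
        self.feature_names = feature_names

    def fit(self, X, y):
        X = validate_data(self, X, ensure_all_finite="allow-nan", dtype=float)
        names = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"f{i}" for i in range(X.shape[1])]
        )
        if self.model_spec is not None:
            self.model_spec_ = self.model_spec
        elif self.tune_budget > 0:
            self.model_spec_ = tune(
                X, y, budget=self.tune_budget, seed=self.random_state
            )
        else:
            self.model_spec_ = ModelSpec()
        self.fit_records_ = resample_fit(
            X,
            y,
            spec=self.model_spec_,
            n_fits=self.n_fits,
            base_seed=self.random_state,
            feature_names=names,
        )
        self.selection_ = select_variants(
            self.fit_records_, threshold=self.threshold, variant_ids=names
        )
        self.appearance_counts_ = self.selection_.table["appearance_count"].to_numpy()
        self.support_ = self.selection_.table["selected"].to_numpy()
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        return tags
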