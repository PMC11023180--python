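"""Correlation expansion of selected variants.

Selection operates on the LD-pruned variant set, so each selected variant
stands in for a linked neighbourhood. This stage recovers the companions:
for every selected (seed) variant, Pearson correlation against every
variant of the full, unpruned matrix is computed over pairwise-complete
samples, and companions at or above the threshold (default r >= 0.97) are
reported.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import GenotypeMatrix

__all__ = ["expand", "CorrelationExpander"]


def _seed_correlations(
    dosage: np.ndarray, seed_col: int, min_complete: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of one column against all columns, pairwise-complete."""
    x = dosage[:, seed_col]
    ok_x = ~np.isnan(x)
    ok = ok_x[:, None] & ~np.isnan(dosage)
    n = ok.sum(axis=0)
    r = np.full(dosage.shape[1], np.nan)
    # loop is over candidate columns with enough complete pairs; vectorising
    # across heterogeneous missingness patterns is not worth the memory
    for j in np.nonzero(n >= max(min_complete, 2))[0]:
        rows = ok[:, j]
        xs = x[rows]
        ys = dosage[rows, j]
        if xs.std() == 0.0 or ys.std() == 0.0:
            continue  # zero-variance companion: r undefined, skipped
        r[j] = np.corrcoef(xs, ys)[0, 1]
    return r, n


def expand(
    selected_ids: Sequence[str],
    full_matrix: GenotypeMatrix,
    r_min: float = 0.97,
    absolute: bool = False,
    min_complete: int = 10,
) -> pd.DataFrame:
    """Find companions correlated with each selected variant.

    Returns a DataFrame (seed_variant_id, companion_variant_id, r,
    n_complete) with companions satisfying ``r >= r_min`` (or
    ``|r| >= r_min`` when ``absolute``), excluding self-pairs and companions
    that are themselves selected. Pairs with fewer than ``min_complete``
    complete samples are skipped with a warning.
    """
    if not 0.0 < r_min <= 1.0:
        raise ValueError("r_min must lie in (0, 1]")
    ids = full_matrix.variant_ids
    index = {v: i for i, v in enumerate(ids)}
    missing = [v for v in selected_ids if v not in index]
    if missing:
        raise KeyError(f"selected ids absent from full matrix: {missing[:5]}")
    selected_set = set(selected_ids)
    hits = []
    n_skipped = 0
    for seed_id in selected_ids:
        r, n = _seed_correlations(full_matrix.dosage, index[seed_id], min_complete)
        n_skipped += int(((n < min_complete) & (n >= 0)).sum() > 0)
        score = np.abs(r) if absolute else r
        for j in np.nonzero(score >= r_min)[0]:
            companion = ids[j]
            if companion == seed_id or companion in selected_set:
                continue
            hits.append((seed_id, companion, float(r[j]), int(n[j])))
    if n_skipped:
        warnings.warn(
            f"{n_skipped} seed(s) had candidate pairs with fewer than "
            f"{min_complete} complete samples; those pairs were skipped"
        )
    return pd.DataFrame(
        hits, columns=["seed_variant_id", "companion_variant_id", "r", "n_complete"]
    )


class CorrelationExpander(BaseEstimator):
    """Estimator wrapper around :func:`expand` for pipeline composition.

    ``fit(X)`` stores the full dosage matrix (columns named via
    ``feature_names`` or ``f{i}``); :meth:`expand` then maps a list of seed
    feature names to their correlated companions.
    """

    def __init__(
        self,
        r_min: float = 0.97,
        absolute: bool = False,
        min_complete: int = 10,
        feature_names: Sequence[str] | None = None,
    ):
        self.r_min = r_min
        self.absolute = absolute
        self.min_complete = min_complete
        self.feature_names = feature_names

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        names = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"f{i}" for i in range(X.shape[1])]
        )
        self.dosage_ = X
        self.feature_names_ = names
        return self

    def expand(self, seed_names: Sequence[str]) -> pd.DataFrame:
        index = {v: i for i, v in enumerate(self.feature_names_)}
        unknown = [s for s in seed_names if s not in index]
        if unknown:
            raise KeyError(f"unknown seed features: {unknown[:5]}")
        # build a lightweight matrix view reusing the generic routine
        fake = GenotypeMatrix.__new__(GenotypeMatrix)
        fake.samples = [f"s{i}" for i in range(self.dosage_.shape[0])]
        fake.variants = pd.DataFrame({"variant_id": self.feature_names_})
        fake.dosage = self.dosage_
        return expand(
            list(seed_names),
            fake,
            r_min=self.r_min,
            absolute=self.absolute,
            min_complete=self.min_complete,
        )
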