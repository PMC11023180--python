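"""Greedy windowed LD pruning of a genotype matrix.

Reproduces the plink ``--indep-pairwise W S r2`` semantics in variant-count
units: within each window of ``window`` consecutive variants (per
chromosome, position order) every retained pair with r² above the threshold
loses its lower-minor-allele-frequency member, then the window advances by
``step`` variants. r² is the squared Pearson correlation of additive
dosages over pairwise-complete samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .datatypes import GenotypeMatrix

__all__ = ["ld_prune", "pairwise_r2", "LDPruner"]


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete samples.

    Pairs with fewer than 2 complete observations, or with zero variance in
    either column, yield 0 (r² undefined → treated as no linkage).
    """
    complete = ~(np.isnan(x) | np.isnan(y))
    if complete.sum() < 2:
        return 0.0
    xs, ys = x[complete], y[complete]
    sx, sy = xs.std(), ys.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _minor_allele_freq(dosage: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(dosage, axis=0) / 2.0
    mean = np.nan_to_num(mean, nan=0.0)
    return np.minimum(mean, 1.0 - mean)


def window_r2_matrix(dosage: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Pairwise-complete r² matrix for a set of columns.

    Computed from masked cross-products so the whole window is a handful of
    matrix multiplications; pairs with <2 complete samples or zero variance
    get r² = 0.
    """
    X = dosage[:, cols]
    M = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X, nan=0.0)
    X2 = X0 * X0
    n = M.T @ M
    sx = X0.T @ M  # sum of x over pairwise-complete rows (per pair)
    sxx = X2.T @ M
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx * sx / n
        denom = varx * varx.T
        r2 = np.where(denom > 0, cov * cov / denom, 0.0)
    r2[n < 2] = 0.0
    return np.nan_to_num(r2, nan=0.0)


def _prune_indices(
    dosage: np.ndarray,
    order: np.ndarray,
    window: int,
    step: int,
    r2_max: float,
    positions: np.ndarray | None = None,
    window_kb: float | None = None,
) -> np.ndarray:
    """Greedy pruning over one chromosome; returns retained row positions.

    With ``window_kb`` set, the window at each step covers the variants
    within that physical distance of the step's first variant instead of a
    fixed variant count.
    """
    maf = _minor_allele_freq(dosage)
    variances = np.nanvar(dosage, axis=0)
    retained = np.ones(len(order), dtype=bool)
    n = len(order)
    for start in range(0, n, step):
        if window_kb is not None:
            span = positions[start:] - positions[start] <= window_kb * 1000.0
            window = int(span.sum())
        win = order[start : start + window]
        r2 = window_r2_matrix(dosage, win)
        for a_pos in range(len(win)):
            if not retained[start + a_pos]:
                continue
            col_a = win[a_pos]
            if variances[col_a] == 0 or np.isnan(variances[col_a]):
                continue  # monomorphic: never a dropper, never dropped
            for b_pos in range(a_pos + 1, len(win)):
                if not retained[start + b_pos]:
                    continue
                col_b = win[b_pos]
                if variances[col_b] == 0 or np.isnan(variances[col_b]):
                    continue
                if r2[a_pos, b_pos] > r2_max:
                    # drop the lower-MAF member; tie -> the later position
                    if maf[col_a] < maf[col_b]:
                        retained[start + a_pos] = False
                        break  # col_a gone; stop pairing it
                    else:
                        retained[start + b_pos] = False
        if start + window >= n:
            break
    return order[retained]


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.1,
    window_kb: float | None = None,
) -> list[str]:
    """Return the variant ids retained by greedy windowed LD pruning.

    ``window`` counts variants; pass ``window_kb`` instead to read the
    window as a physical distance in kilobases (the step stays in
    variants).
    """
    if step < 1 or (window_kb is None and window < step):
        raise ValueError("require window >= step >= 1")
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must lie in (0, 1]")
    retained_ids: list[str] = []
    variants = matrix.variants
    for chrom in pd.unique(variants["chrom"]):
        on_chrom = np.nonzero((variants["chrom"] == chrom).to_numpy())[0]
        pos = variants["pos"].to_numpy()[on_chrom]
        by_pos = on_chrom[np.argsort(pos, kind="stable")]
        kept = _prune_indices(
            matrix.dosage,
            by_pos,
            window,
            step,
            r2_max,
            positions=np.sort(pos),
            window_kb=window_kb,
        )
        retained_ids.extend(variants["variant_id"].iloc[np.sort(kept)])
    return retained_ids


class LDPruner(SelectorMixin, BaseEstimator):
    """scikit-learn transformer applying greedy windowed LD pruning.

    Operates on a plain samples x variants dosage array (NaN = missing);
    column order is taken as genome order on one chromosome. For
    multi-chromosome data use :func:`ld_prune` on a
    :class:`~traitboost.datatypes.GenotypeMatrix`.

    Parameters
    ----------
    window, step : int
        Window length and advance, in variants.
    r2_max : float
        Retained pairs within a window never exceed this squared Pearson
        correlation.
    """

    def __init__(self, window: int = 50, step: int = 10, r2_max: float = 0.1):
        self.window = window
        self.step = step
        self.r2_max = r2_max

    def fit(self, X, y=None):
        if self.step < 1 or self.window < self.step:
            raise ValueError("require window >= step >= 1")
        if not 0.0 < self.r2_max <= 1.0:
            raise ValueError("r2_max must lie in (0, 1]")
        X = validate_data(self, X, ensure_all_finite="allow-nan", dtype=float)
        order = np.arange(X.shape[1])
        kept = _prune_indices(X, order, self.window, self.step, self.r2_max)
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[kept] = True
        self.support_ = mask
        self.n_retained_ = int(mask.sum())
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def _more_tags(self):
        return {"allow_nan": True}

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        tags.target_tags.required = False
        return tags
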