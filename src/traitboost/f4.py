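"""F4 allele-sharing statistics with block-jackknife standard errors.

For a quartet (A, B, C, D) of populations the statistic is the
across-variant mean of (p_A − p_B)(p_C − p_D). Under a tree ((A,B),(C,D))
with no gene flow its expectation is zero; a significantly positive value
indicates allele sharing between B and D (or A and C), a significantly
negative one between B and C. Standard errors come from a delete-one-block
jackknife over contiguous variant blocks, weighted by block size, and
p-values from the normal approximation to z = f4/se.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix

__all__ = [
    "PopulationFrequencies",
    "F4Result",
    "population_frequencies",
    "f4",
    "build_quartets",
]


@dataclass
class PopulationFrequencies:
    """Alternative-allele frequencies per population with jackknife blocks."""

    populations: list[str]
    freq: np.ndarray  # populations x variants
    counts: np.ndarray  # haploid called-allele counts, populations x variants
    blocks: np.ndarray  # per-variant contiguous block index
    variant_ids: list[str]

    def __post_init__(self) -> None:
        if self.freq.shape != self.counts.shape:
            raise ValueError("freq and counts shapes differ")
        if self.freq.shape[1] != len(self.blocks):
            raise ValueError("blocks length inconsistent with variants")

    def index_of(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None


@dataclass
class F4Result:
    """F4 estimate for one quartet with jackknife error and interpretation."""

    quartet: tuple[str, str, str, str]
    f4: float
    se: float
    z: float
    p: float
    n_variants_used: int
    interpretation: str  # "B-D flow", "B-C flow", or "none"

    def as_row(self) -> dict:
        a, b, c, d = self.quartet
        return {
            "A": a,
            "B": b,
            "C": c,
            "D": d,
            "f4": self.f4,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "n": self.n_variants_used,
            "interpretation": self.interpretation,
        }


def population_frequencies(
    matrix: GenotypeMatrix,
    popmap: dict[str, str],
    block_size: int = 500,
) -> PopulationFrequencies:
    """Tally per-population alternative-allele frequencies.

    Frequency is (sum of dosages) / (2 x called samples) per population and
    variant. Variants for which any population has zero called samples are
    dropped. Jackknife blocks are contiguous runs of ``block_size`` variants
    per chromosome.
    """
    unmapped = [s for s in matrix.samples if s not in popmap]
    if unmapped:
        raise ValueError(f"samples missing from population map: {unmapped[:5]}")
    pops = sorted(set(popmap[s] for s in matrix.samples))
    sample_pop = np.array([pops.index(popmap[s]) for s in matrix.samples])
    n_pops = len(pops)
    called = ~np.isnan(matrix.dosage)
    freq = np.zeros((n_pops, matrix.n_variants))
    counts = np.zeros((n_pops, matrix.n_variants))
    for k in range(n_pops):
        rows = sample_pop == k
        if not rows.any():
            raise ValueError(f"empty population {pops[k]!r}")
        n_called = called[rows].sum(axis=0)
        counts[k] = 2 * n_called
        with np.errstate(invalid="ignore"):
            freq[k] = np.nansum(matrix.dosage[rows], axis=0) / np.maximum(counts[k], 1)
    keep = (counts > 0).all(axis=0)
    freq, counts = freq[:, keep], counts[:, keep]
    kept_variants = matrix.variants.loc[keep]
    blocks = np.empty(int(keep.sum()), dtype=int)
    offset = 0
    next_block = 0
    for chrom in pd.unique(kept_variants["chrom"]):
        m = int((kept_variants["chrom"] == chrom).sum())
        local = np.arange(m) // block_size + next_block
        blocks[offset : offset + m] = local
        offset += m
        next_block = local[-1] + 1
    return PopulationFrequencies(
        populations=pops,
        freq=freq,
        counts=counts,
        blocks=blocks,
        variant_ids=list(kept_variants["variant_id"]),
    )


def _weighted_jackknife_se(values: np.ndarray, blocks: np.ndarray) -> float:
    """Delete-one-block jackknife SE of the mean, block-size weighted.

    Uses the unequal-block-size jackknife variance (Busing et al. 1999):
    with n values in m blocks of sizes m_j and h_j = n/m_j,

        theta_J = m*theta - sum_j (1 - m_j/n) * theta_{-j}
        var = (1/m) sum_j (h_j*theta - (h_j-1)*theta_{-j} - theta_J)^2 / (h_j - 1)
    """
    n = len(values)
    total = values.sum()
    theta = total / n
    block_ids, inverse = np.unique(blocks, return_inverse=True)
    m = len(block_ids)
    if m < 2:
        raise ValueError("need >= 2 jackknife blocks")
    block_sums = np.bincount(inverse, weights=values)
    block_sizes = np.bincount(inverse).astype(float)
    loo = (total - block_sums) / (n - block_sizes)  # theta_{-j}
    h = n / block_sizes
    theta_j = m * theta - ((1.0 - block_sizes / n) * loo).sum()
    pseudo = h * theta - (h - 1.0) * loo
    var = np.mean((pseudo - theta_j) ** 2 / (h - 1.0))
    return float(np.sqrt(var))


def f4(
    freqs: PopulationFrequencies,
    quartet: tuple[str, str, str, str],
    method: str = "afprod",
) -> F4Result:
    """F4(A, B, C, D) with block-jackknife SE.

    ``method="afprod"`` averages the frequency products
    (p_A − p_B)(p_C − p_D) directly; ``method="f2"`` assembles the same
    quantity from pairwise f2 distances,
    (f2(A,D) + f2(B,C) − f2(A,C) − f2(B,D)) / 2 — the per-population
    sampling terms cancel in this combination, so the two routes agree and
    serve as an internal cross-check.
    """
    a, b, c, d = quartet
    if len({a, b, c, d}) != 4:
        raise ValueError("quartet populations must be distinct")
    ia, ib, ic, id_ = (freqs.index_of(x) for x in quartet)
    pa, pb, pc, pd_ = (freqs.freq[i] for i in (ia, ib, ic, id_))
    if method == "afprod":
        values = (pa - pb) * (pc - pd_)
    elif method == "f2":
        values = (
            (pa - pd_) ** 2 + (pb - pc) ** 2 - (pa - pc) ** 2 - (pb - pd_) ** 2
        ) / 2.0
    else:
        raise ValueError("method must be 'afprod' or 'f2'")
    est = float(values.mean())
    se = _weighted_jackknife_se(values, freqs.blocks)
    if se == 0.0:
        z = 0.0 if est == 0.0 else np.sign(est) * np.inf
    else:
        z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    if p < 0.05 and est > 0:
        interp = "B-D flow"
    elif p < 0.05 and est < 0:
        interp = "B-C flow"
    else:
        interp = "none"
    return F4Result(
        quartet=quartet,
        f4=est,
        se=se,
        z=float(z),
        p=p,
        n_variants_used=len(values),
        interpretation=interp,
    )


def build_quartets(
    populations: list[str],
    outgroup: str,
    hypotheses: list[tuple[str, str, str]],
) -> list[tuple[str, str, str, str]]:
    """Turn migration hypotheses into F4 quartets.

    Each hypothesis is (source B, sister C, target D); the outgroup always
    sits in the A position. Hypotheses naming unknown populations raise;
    duplicates are dropped with a warning. This evaluates user-supplied
    hypotheses — it does not infer an admixture graph.
    """
    known = set(populations)
    if outgroup not in known:
        raise ValueError(f"outgroup {outgroup!r} not among populations")
    quartets: list[tuple[str, str, str, str]] = []
    seen = set()
    for triple in hypotheses:
        b, c, d = triple
        for pop in triple:
            if pop not in known:
                raise ValueError(f"hypothesis references unknown population {pop!r}")
        q = (outgroup, b, c, d)
        if q in seen:
            warnings.warn(f"duplicate hypothesis {triple} dropped")
            continue
        seen.add(q)
        quartets.append(q)
    return quartets
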