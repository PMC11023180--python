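"""Core in-memory containers shared across the pipeline.

Genotypes are held as an additive dosage matrix (samples x variants) with
``NaN`` marking missing calls; the companion variant table is a pandas
DataFrame carrying one row per variant in matrix column order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: INFO metrics consumed by the hard-filter stage.
INFO_METRICS = (
    "AC",
    "MQ",
    "DP",
    "SOR",
    "QD",
    "FS",
    "MQRankSum",
    "ReadPosRankSum",
    "BaseQRankSum",
)

VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "ref", "alt", "n_alt_alleles")


def make_variant_table(
    chrom: Sequence[str],
    pos: Sequence[int],
    ref: Sequence[str],
    alt: Sequence[str],
    info: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assemble a variant table with ``Chrom_PosN``-style unique identifiers."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    if np.any(pos < 1):
        raise ValueError("positions are 1-based and must be >= 1")
    ids = [f"{c}_Pos{p}" for c, p in zip(chrom, pos)]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant identifiers (chrom_pos must be unique)")
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos,
            "ref": list(ref),
            "alt": list(alt),
        }
    )
    table["n_alt_alleles"] = [1 if "," not in a else a.count(",") + 1 for a in table["alt"]]
    for key, values in (info or {}).items():
        table[key] = np.asarray(values, dtype=float)
    return table


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix.

    ``dosage`` is float with entries in {0, 1, 2} and ``NaN`` for missing
    genotypes (the ``additive_NA`` coding). :meth:`to_heatmap_coding` returns
    the integer −1/0/1/2 recode used for genotype-distribution heatmaps.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        observed = self.dosage[~np.isnan(self.dosage)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def to_heatmap_coding(self) -> np.ndarray:
        """Integer recode: 0 hom-ref, 1 het, 2 hom-alt, −1 missing."""
        coded = np.where(np.isnan(self.dosage), -1.0, self.dosage)
        return coded.astype(np.int8)

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to the given variants, preserving their requested order."""
        index = pd.Index(self.variants["variant_id"])
        locs = index.get_indexer(list(variant_ids))
        if (locs < 0).any():
            missing = [v for v, l in zip(variant_ids, locs) if l < 0]
            raise KeyError(f"unknown variant ids: {missing[:5]}")
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[locs].reset_index(drop=True),
            dosage=self.dosage[:, locs],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.samples)}
        try:
            rows = [order[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"unknown sample id: {exc.args[0]}") from exc
        return GenotypeMatrix(
            samples=list(sample_ids),
            variants=self.variants.copy(),
            dosage=self.dosage[rows],
        )
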