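"""VCF / phenotype / population-map ingestion, hard filtering, and
phenotype classification.

The hard-filter stage mirrors GATK-style expression filtering: each
expression is ``metric cmp constant`` and a variant must satisfy *all*
expressions (and be biallelic) to be kept.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import INFO_METRICS, GenotypeMatrix, make_variant_table

__all__ = [
    "DEFAULT_HARD_FILTERS",
    "read_vcf",
    "read_phenotype_table",
    "read_population_map",
    "hard_filter",
    "classify_phenotype",
]

#: Default GATK-style hard-filter expression set (ten expressions over nine
#: INFO metrics; DP is bounded on both sides).
DEFAULT_HARD_FILTERS = (
    "AC > 10",
    "MQ > 30.0",
    "DP > 1525",
    "DP < 9150",
    "SOR < 3.0",
    "QD > 2.0",
    "FS < 60.0",
    "MQRankSum > -12.5",
    "ReadPosRankSum > -8.0",
    "BaseQRankSum > -12.5",
)

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN/missing, 3=HOM_ALT
_GT_TYPE_TO_DOSAGE = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}


def read_vcf(
    path: str | Path,
    info_metrics: Sequence[str] = INFO_METRICS,
    on_multiallelic: str = "error",
) -> GenotypeMatrix:
    """Read a VCF into an additive-dosage :class:`GenotypeMatrix`.

    Dosage is the alternative-allele count of the GT field (0/0 → 0,
    0/1 → 1, 1/1 → 2, ./. → NaN). Multiallelic records raise by default;
    pass ``on_multiallelic="skip"`` to drop them with a warning.
    """
    if on_multiallelic not in ("error", "skip"):
        raise ValueError("on_multiallelic must be 'error' or 'skip'")
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    info: dict[str, list[float]] = {k: [] for k in info_metrics}
    rows: list[np.ndarray] = []
    n_multi = 0
    for record in vcf:
        if len(record.ALT) != 1:
            if on_multiallelic == "error":
                raise ValueError(
                    f"multiallelic record at {record.CHROM}:{record.POS}; "
                    "split or normalise the VCF, or pass on_multiallelic='skip'"
                )
            n_multi += 1
            continue
        chroms.append(record.CHROM)
        positions.append(record.POS)
        refs.append(record.REF)
        alts.append(record.ALT[0])
        for key in info_metrics:
            value = record.INFO.get(key)
            info[key].append(float(value) if value is not None else np.nan)
        gt = np.array(
            [_GT_TYPE_TO_DOSAGE[int(t)] for t in record.gt_types], dtype=float
        )
        rows.append(gt)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic records")
    if not rows:
        raise ValueError(f"no biallelic records found in {path}")
    variants = make_variant_table(
        chroms, positions, refs, alts, info={k: np.array(v) for k, v in info.items()}
    )
    dosage = np.stack(rows, axis=1)
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with sample ids in the first column, one column per trait."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sample id to population label."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table.iloc[:, 0].astype(str).to_dict()


_EXPR_RE = re.compile(r"^\s*(\w+)\s*([<>])\s*(-?\d+(?:\.\d+)?)\s*$")


def parse_filter_expression(expression: str) -> tuple[str, str, float]:
    match = _EXPR_RE.match(expression)
    if match is None:
        raise ValueError(
            f"cannot parse filter expression {expression!r}; expected 'metric < x' or 'metric > x'"
        )
    metric, cmp, value = match.groups()
    return metric, cmp, float(value)


def hard_filter(
    variants: pd.DataFrame,
    expressions: Sequence[str] = DEFAULT_HARD_FILTERS,
) -> pd.DataFrame:
    """Keep biallelic variants satisfying *all* filter expressions.

    Order is preserved; the result is always a subset of the input. An
    expression naming a metric absent from the table raises. Records with a
    missing (NaN) metric value fail that expression, matching the
    conservative reading of hard filtering.
    """
    keep = np.ones(len(variants), dtype=bool)
    if "n_alt_alleles" in variants.columns:
        keep &= variants["n_alt_alleles"].to_numpy() == 1
    for expression in expressions:
        metric, cmp, value = parse_filter_expression(expression)
        if metric not in variants.columns:
            raise ValueError(f"filter expression references unknown metric {metric!r}")
        column = variants[metric].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            keep &= (column > value) if cmp == ">" else (column < value)
    return variants.loc[keep].copy()


def classify_phenotype(
    raw_values: pd.Series,
    class_ranges: tuple,
    trait_name: str | None = None,
) -> pd.Series:
    """Binarise a raw phenotype by two value ranges or two category labels.

    ``class_ranges`` is either ``((lo0, hi0), (lo1, hi1))`` for a numeric
    trait (inclusive bounds, e.g. early vs late bolting in days) or
    ``("Green", "Purple")`` for a categorical one. Values in range/label 0
    map to class 0, in range/label 1 to class 1, and anything else is
    excluded (NaN) — samples between the two ranges do not enter the trait.
    """
    r0, r1 = class_ranges
    values = raw_values
    out = pd.Series(np.nan, index=values.index, name=trait_name or raw_values.name)
    if isinstance(r0, (tuple, list)):
        (lo0, hi0), (lo1, hi1) = r0, r1
        if max(lo0, lo1) <= min(hi0, hi1):
            raise ValueError(f"class ranges {r0} and {r1} overlap")
        numeric = pd.to_numeric(values, errors="coerce")
        out[(numeric >= lo0) & (numeric <= hi0)] = 0
        out[(numeric >= lo1) & (numeric <= hi1)] = 1
    else:
        if r0 == r1:
            raise ValueError("class labels must differ")
        out[values == r0] = 0
        out[values == r1] = 1
    return out
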