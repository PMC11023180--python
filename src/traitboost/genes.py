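"""Variant-to-gene assignment with region classification, and the
genotype-distribution clustering behind trait heatmaps.

Region taxonomy (strand-aware, 1-based inclusive coordinates):
``exon_cds``, ``utr5``, ``utr3``, ``intron``, ``upstream``, ``downstream``,
``intergenic``. UTRs are derived as exon minus CDS when the annotation does
not state them explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "GeneModel",
    "read_gff3",
    "annotate_variants",
    "candidate_genes",
    "genotype_heatmap_order",
]

REGION_PRIORITY = {
    "exon_cds": 0,
    "utr5": 1,
    "utr3": 1,
    "intron": 2,
    "upstream": 3,
    "downstream": 3,
    "intergenic": 9,
}


@dataclass
class GeneModel:
    """One gene with exon/CDS intervals (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for lo, hi in self.exons:
            if lo < self.start or hi > self.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")

    def classify_position(self, pos: int, window: int) -> tuple[str, int] | None:
        """Region and distance of a position relative to this gene.

        Distance is 0 for genic regions and the gap to the gene boundary for
        up/downstream. Returns None when the position is farther than
        ``window`` from the gene."""
        if self.start <= pos <= self.end:
            in_exon = any(lo <= pos <= hi for lo, hi in self.exons)
            if not in_exon:
                return "intron", 0
            if any(lo <= pos <= hi for lo, hi in self.cds):
                return "exon_cds", 0
            if not self.cds:
                return "utr5", 0  # exon with no CDS: treat as untranslated
            cds_lo = min(lo for lo, _ in self.cds)
            cds_hi = max(hi for _, hi in self.cds)
            if pos < cds_lo:
                return ("utr5", 0) if self.strand == "+" else ("utr3", 0)
            if pos > cds_hi:
                return ("utr3", 0) if self.strand == "+" else ("utr5", 0)
            return "intron", 0  # between CDS chunks but inside an exon gap
        if pos < self.start and self.start - pos <= window:
            dist = self.start - pos
            return ("upstream", dist) if self.strand == "+" else ("downstream", dist)
        if pos > self.end and pos - self.end <= window:
            dist = pos - self.end
            return ("downstream", dist) if self.strand == "+" else ("upstream", dist)
        return None


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from a GFF3 file (gene/mRNA/exon/CDS features)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = [
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        ]
        cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=exons,
                cds=cds,
            )
        )
    return genes


def annotate_variants(
    variants: pd.DataFrame,
    genes: list[GeneModel],
    window: int = 5000,
) -> pd.DataFrame:
    """Classify each variant into exactly one region.

    A variant hitting several genes reports the highest-priority region
    (exon_cds > utr > intron > up/downstream), breaking ties by distance to
    the nearest gene start. Variants on chromosomes without annotation are
    intergenic (with a warning). Returns a DataFrame with columns
    variant_id, gene_id (None for intergenic), region, distance.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    unknown_chroms = set()
    rows = []
    for rec in variants.itertuples(index=False):
        candidates = by_chrom.get(rec.chrom)
        if candidates is None:
            unknown_chroms.add(rec.chrom)
            rows.append((rec.variant_id, None, "intergenic", np.nan))
            continue
        best = None
        for gene in candidates:
            hit = gene.classify_position(int(rec.pos), window)
            if hit is None:
                continue
            region, dist = hit
            key = (REGION_PRIORITY[region], abs(int(rec.pos) - gene.start))
            if best is None or key < best[0]:
                best = (key, gene.gene_id, region, dist)
        if best is None:
            rows.append((rec.variant_id, None, "intergenic", np.nan))
        else:
            rows.append((rec.variant_id, best[1], best[2], best[3]))
    if unknown_chroms:
        warnings.warn(
            f"variants on unannotated chromosomes treated as intergenic: {sorted(unknown_chroms)}"
        )
    return pd.DataFrame(rows, columns=["variant_id", "gene_id", "region", "distance"])


def candidate_genes(annotations: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by the number of selected/expanded variants they carry.

    Genes with more variants rank first; ties break alphabetically. Regions
    are aggregated per gene. Intergenic variants do not contribute.
    """
    genic = annotations.dropna(subset=["gene_id"])
    if genic.empty:
        return pd.DataFrame(columns=["gene_id", "n_variants", "regions", "variant_ids"])
    grouped = (
        genic.groupby("gene_id")
        .agg(
            n_variants=("variant_id", "size"),
            regions=("region", lambda r: ",".join(sorted(set(r)))),
            variant_ids=("variant_id", lambda v: ",".join(v)),
        )
        .reset_index()
    )
    return grouped.sort_values(
        ["n_variants", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)


def _cluster_order(data: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    if data.shape[0] < 2:
        return np.arange(data.shape[0]), None
    link = linkage(pdist(data, metric="euclidean"), method="complete")
    return np.asarray(leaves_list(link)), link


def genotype_heatmap_order(
    coded: np.ndarray,
    labels: np.ndarray,
) -> dict:
    """Row/column orders for a genotype-distribution heatmap.

    ``coded`` is the −1/0/1/2 recode restricted to the selected variants
    (missing treated as an ordinary value); accessions (rows) are clustered
    hierarchically *within* each phenotype group and variants (columns)
    across all accessions, using Euclidean distance with complete linkage.
    Returns row_order (class-0 block first), col_order, and the linkage
    trees per group and for columns.
    """
    coded = np.asarray(coded, dtype=float)
    labels = np.asarray(labels)
    row_order: list[int] = []
    row_linkages = {}
    for cls in sorted(np.unique(labels)):
        rows = np.nonzero(labels == cls)[0]
        order, link = _cluster_order(coded[rows])
        row_order.extend(rows[order])
        row_linkages[cls] = link
    col_order, col_link = _cluster_order(coded.T)
    return {
        "row_order": np.array(row_order, dtype=int),
        "col_order": np.asarray(col_order, dtype=int),
        "row_linkages": row_linkages,
        "col_linkage": col_link,
    }
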