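"""Synthetic genotype/phenotype study generator with planted ground truth.

Emulates a resequencing panel of a few hundred accessions drawn from several
structured populations: allele frequencies drift from a common ancestor under
a Balding–Nichols model (per-population Beta draws whose variance is
p(1−p)·F), optional admixture events mix population frequency vectors, and
genotypes are binomial draws with local LD blocks, missing calls, and a
binary trait driven by a small set of causal variants through a liability
(logistic) model.

The generator exists so that downstream stages — hard filtering, LD pruning,
resampled gradient-boosting selection, correlation expansion, gene
assignment and F4 statistics — can be exercised against a known truth set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import GenotypeMatrix, make_variant_table

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_allele_frequencies",
    "simulate_genotypes",
    "simulate_binary_trait",
    "simulate_study",
    "write_fixture",
]

# pass-region sampling windows for synthetic INFO metrics, and the value
# planted when a variant is chosen to fail that metric's hard filter
_INFO_PASS = {
    "MQ": (40.0, 60.0, 25.0),
    "DP": (2000.0, 9000.0, 1000.0),
    "SOR": (0.5, 2.5, 4.0),
    "QD": (5.0, 30.0, 1.0),
    "FS": (0.0, 20.0, 80.0),
    "MQRankSum": (-3.0, 3.0, -15.0),
    "ReadPosRankSum": (-3.0, 3.0, -10.0),
    "BaseQRankSum": (-3.0, 3.0, -15.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic panel.

    Defaults describe the reference test regime: 4 populations x 75 samples
    (300 accessions), 5 000 biallelic variants on one chromosome, moderate
    drift (F = 0.1), LD blocks of 5 variants, 2% missing calls, and a binary
    trait driven by 10 causal variants at 1.5 log-odds per alternative
    allele copy.
    """

    n_samples_per_pop: int = 75
    n_pops: int = 4
    n_variants: int = 5000
    fst: float = 0.1
    admixture_events: tuple[tuple[int, int, float], ...] = ()
    n_causal: int = 10
    effect_size: float = 1.5
    ld_block_size: int = 5
    ld_decay: float = 0.1
    missing_rate: float = 0.02
    info_fail_fraction: float = 0.1
    chrom: str = "Chr1"
    variant_spacing_bp: int = 200
    tagged_truth: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples_per_pop", "n_pops", "n_variants", "ld_block_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_causal < 0:
            raise ValueError("n_causal must be >= 0")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in the open interval (0, 1)")
        for src, tgt, alpha in self.admixture_events:
            if not 0.0 <= alpha <= 1.0:
                raise ValueError("admixture proportion must lie in [0, 1]")
            for pop in (src, tgt):
                if not 0 <= pop < self.n_pops:
                    raise ValueError(f"admixture event references unknown population {pop}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.ld_decay <= 1.0:
            raise ValueError("ld_decay must lie in [0, 1]")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_pop * self.n_pops

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TruthRecord:
    """Planted ground truth emitted alongside a simulated panel."""

    causal_variant_ids: list[str]
    effects: dict[str, float]
    admixture_events: list[tuple[int, int, float]]
    population_assignments: dict[str, str]
    causal_indices: list[int] = field(default_factory=list)
    block_of: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "causal_variant_ids": self.causal_variant_ids,
            "effects": self.effects,
            "admixture_events": [list(e) for e in self.admixture_events],
            "population_assignments": self.population_assignments,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def pop_label(index: int) -> str:
    return f"POP{index}"


def simulate_allele_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ancestral and per-population alternative-allele frequencies.

    Ancestral frequencies are uniform on [0.05, 0.95]; each population's
    frequency is a Beta draw with mean equal to the ancestral frequency and
    variance p(1−p)·F (Balding–Nichols). Admixture events then replace the
    target population's frequency vector by ``alpha·source + (1−alpha)·target``
    in the order given.

    Returns ``(ancestral, freqs)`` with ``freqs`` of shape
    (n_pops, n_variants).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    p_anc = rng.uniform(0.05, 0.95, size=config.n_variants)
    f = config.fst
    # Beta(a, b) with a + b = (1 - F) / F has mean p and variance p(1-p)F
    scale = (1.0 - f) / f
    freqs = rng.beta(
        p_anc * scale, (1.0 - p_anc) * scale, size=(config.n_pops, config.n_variants)
    )
    for src, tgt, alpha in config.admixture_events:
        freqs[tgt] = alpha * freqs[src] + (1.0 - alpha) * freqs[tgt]
    return p_anc, freqs


def _block_leaders(config: SimConfig) -> np.ndarray:
    """Index of the block-leader (copy-source) column for every variant."""
    idx = np.arange(config.n_variants)
    return (idx // config.ld_block_size) * config.ld_block_size


def simulate_genotypes(
    freqs: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Draw genotypes and plant the causal truth set.

    Genotypes are Binomial(2, p_pop) per sample; consecutive variants are
    grouped into LD blocks of ``ld_block_size`` in which every non-leader
    column copies the block leader entrywise, redrawing each entry
    independently with probability ``ld_decay``. Causal variants are drawn
    independently (removed from their block) unless ``tagged_truth`` is set,
    in which case they are placed as block leaders so their block mates act
    as r²-controlled proxies. Missing calls are masked uniformly at
    ``missing_rate`` after the trait-relevant dosages are fixed.
    """
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n_pops, n_variants = freqs.shape
    n = config.n_samples
    pop_of_sample = np.repeat(np.arange(n_pops), config.n_samples_per_pop)
    p_sample = freqs[pop_of_sample]  # (n_samples, n_variants)

    leaders = _block_leaders(config)
    causal_idx = np.sort(
        rng.choice(n_variants, size=config.n_causal, replace=False)
    ).astype(int)
    if config.tagged_truth:
        # plant causal variants as block leaders: their block mates tag them
        causal_idx = np.unique(leaders[causal_idx])
        if len(causal_idx) < config.n_causal:
            extra = np.setdiff1d(np.unique(leaders), causal_idx)
            take = rng.choice(extra, size=config.n_causal - len(causal_idx), replace=False)
            causal_idx = np.sort(np.concatenate([causal_idx, take]))

    fresh = rng.binomial(2, p_sample).astype(float)
    dosage = fresh[:, leaders].copy()
    redraw = rng.random((n, n_variants)) < config.ld_decay
    dosage[redraw] = fresh[redraw]
    is_leader = leaders == np.arange(n_variants)
    dosage[:, is_leader] = fresh[:, is_leader]
    if not config.tagged_truth:
        # causal columns leave their LD block: independent draws, and block
        # mates fall back on untagged noise
        dosage[:, causal_idx] = rng.binomial(2, p_sample[:, causal_idx]).astype(float)

    samples = [f"S{i:04d}" for i in range(n)]
    pos = 1 + config.variant_spacing_bp * np.arange(n_variants)
    ref = np.full(n_variants, "A", dtype=object)
    alt = np.full(n_variants, "T", dtype=object)
    variants = make_variant_table(
        [config.chrom] * n_variants, pos, ref, alt
    )
    matrix = GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)

    ids = matrix.variant_ids
    truth = TruthRecord(
        causal_variant_ids=[ids[i] for i in causal_idx],
        effects={ids[i]: config.effect_size for i in causal_idx},
        admixture_events=list(config.admixture_events),
        population_assignments={
            s: pop_label(p) for s, p in zip(samples, pop_of_sample)
        },
        causal_indices=[int(i) for i in causal_idx],
        block_of={ids[i]: int(leaders[i] // config.ld_block_size) for i in range(n_variants)},
    )

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        matrix.dosage[mask] = np.nan
    return matrix, truth


def simulate_binary_trait(
    matrix: GenotypeMatrix,
    truth: TruthRecord,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    trait_name: str = "trait",
    offset: float | None = None,
) -> pd.DataFrame:
    """Draw a binary trait from a liability (logistic) model.

    Liability is the sum of ``effect x dosage`` over causal variants, with
    missing dosages contributing 0. The offset defaults to the median
    liability, which keeps the marginal class balance near 0.5 (within
    [0.35, 0.65] under the default regime); pass ``offset`` explicitly to
    place the decision point elsewhere. Class 1 is drawn with probability
    ``sigmoid(liability − offset)``.

    Returns a one-column DataFrame (trait name) indexed by sample id with
    integer classes in {0, 1}.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    liability = np.zeros(matrix.n_samples)
    if truth.causal_variant_ids:
        sub = matrix.subset_variants(truth.causal_variant_ids)
        effects = np.array([truth.effects[v] for v in sub.variant_ids])
        dos = np.nan_to_num(sub.dosage, nan=0.0)
        liability = dos @ effects
    offset = float(np.median(liability)) if offset is None else float(offset)
    prob = expit(liability - offset)
    labels = (rng.random(matrix.n_samples) < prob).astype(int)
    return pd.DataFrame({trait_name: labels}, index=pd.Index(matrix.samples, name="sample"))


def simulate_study(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """One-call generator: frequencies → genotypes → trait."""
    rng = np.random.default_rng(config.seed)
    _, freqs = simulate_allele_frequencies(config, rng)
    matrix, truth = simulate_genotypes(freqs, config, rng)
    trait = simulate_binary_trait(matrix, truth, config, rng)
    return matrix, trait, truth


def _synthetic_info(
    matrix: GenotypeMatrix,
    truth: TruthRecord,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw INFO metrics; a configurable fraction of non-causal variants is
    planted to fail exactly one randomly chosen hard-filter expression."""
    m = matrix.n_variants
    info: dict[str, np.ndarray] = {}
    for key, (lo, hi, _fail) in _INFO_PASS.items():
        info[key] = np.round(rng.uniform(lo, hi, size=m), 3)
    info["AC"] = np.nansum(matrix.dosage, axis=0).astype(float)

    causal = set(truth.causal_indices)
    eligible = np.array([i for i in range(m) if i not in causal], dtype=int)
    n_fail = int(round(config.info_fail_fraction * len(eligible)))
    if n_fail:
        fail_idx = rng.choice(eligible, size=n_fail, replace=False)
        keys = list(_INFO_PASS)
        which = rng.integers(0, len(keys), size=n_fail)
        for i, k in zip(fail_idx, which):
            info[keys[k]][i] = _INFO_PASS[keys[k]][2]
    return info


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_fixture(
    matrix: GenotypeMatrix,
    trait: pd.DataFrame,
    truth: TruthRecord,
    config: SimConfig,
    out_dir: str | Path,
    gene_spacing_bp: int = 10_000,
    gene_length_bp: int = 3_000,
) -> dict[str, Path]:
    """Write the panel as VCF 4.2 + phenotype TSV + population TSV + GFF3 +
    truth JSON.

    Genotypes are unphased ("0/0", "0/1", "1/1", "./."); INFO carries the
    synthetic AC/MQ/DP/SOR/QD/FS/*RankSum metrics. Genes are tiled along the
    chromosome every ``gene_spacing_bp`` with a single mRNA whose exons/CDS
    leave intronic and UTR intervals, so region classification can be
    exercised. Returns a name → path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 3)
    info = _synthetic_info(matrix, truth, config, rng)

    vcf_path = out / "variants.vcf"
    coded = matrix.to_heatmap_coding()
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        max_pos = int(matrix.variants["pos"].max()) + gene_spacing_bp
        fh.write(f"##contig=<ID={config.chrom},length={max_pos}>\n")
        for key in info:
            number = "A" if key == "AC" else "1"
            num_type = "Integer" if key in ("AC", "DP") else "Float"
            fh.write(
                f'##INFO=<ID={key},Number={number},Type={num_type},Description="synthetic {key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        for j, row in enumerate(matrix.variants.itertuples(index=False)):
            pairs = []
            for key in info:
                v = info[key][j]
                pairs.append(f"{key}={int(v)}" if key in ("AC", "DP") else f"{key}={v:g}")
            gts = "\t".join(
                _GT_STRING[g] if g >= 0 else "./." for g in coded[:, j]
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t{';'.join(pairs)}\tGT\t{gts}\n"
            )

    pheno_path = out / "phenotypes.tsv"
    trait.to_csv(pheno_path, sep="\t")

    pop_path = out / "populations.tsv"
    pd.Series(truth.population_assignments, name="population").rename_axis("sample").to_csv(
        pop_path, sep="\t"
    )

    gff_path = out / "genes.gff3"
    _write_tiled_gff3(
        gff_path,
        chrom=config.chrom,
        chrom_length=int(matrix.variants["pos"].max()) + gene_spacing_bp,
        spacing=gene_spacing_bp,
        length=gene_length_bp,
    )

    truth_path = out / "truth.json"
    truth_path.write_text(truth.to_json())
    return {
        "vcf": vcf_path,
        "phenotypes": pheno_path,
        "populations": pop_path,
        "gff3": gff_path,
        "truth": truth_path,
    }


def _write_tiled_gff3(
    path: Path, chrom: str, chrom_length: int, spacing: int, length: int
) -> None:
    """Tile genes of alternating strand along one chromosome.

    Each gene carries one mRNA with two exons separated by an intron; the CDS
    starts/ends inside the exons leaving 5' and 3' UTR stubs.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chrom} 1 {chrom_length}\n")
        gid = 0
        for start in range(1, chrom_length - length, spacing):
            end = start + length - 1
            strand = "+" if gid % 2 == 0 else "-"
            gene = f"gene{gid:04d}"
            exon1 = (start, start + length // 3)
            exon2 = (end - length // 3, end)
            utr = length // 10
            if strand == "+":
                cds = [(exon1[0] + utr, exon1[1]), (exon2[0], exon2[1] - utr)]
            else:
                cds = [(exon1[0] + utr, exon1[1]), (exon2[0], exon2[1] - utr)]
            rows = [
                (chrom, "syn", "gene", start, end, ".", strand, ".", f"ID={gene}"),
                (chrom, "syn", "mRNA", start, end, ".", strand, ".", f"ID={gene}.m1;Parent={gene}"),
                (chrom, "syn", "exon", exon1[0], exon1[1], ".", strand, ".", f"ID={gene}.e1;Parent={gene}.m1"),
                (chrom, "syn", "exon", exon2[0], exon2[1], ".", strand, ".", f"ID={gene}.e2;Parent={gene}.m1"),
                (chrom, "syn", "CDS", cds[0][0], cds[0][1], ".", strand, "0", f"ID={gene}.c1;Parent={gene}.m1"),
                (chrom, "syn", "CDS", cds[1][0], cds[1][1], ".", strand, "0", f"ID={gene}.c2;Parent={gene}.m1"),
            ]
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")
            gid += 1
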