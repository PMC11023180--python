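import numpy as np
import pandas as pd
import pytest

import traitboost as tb
from traitboost.datatypes import make_variant_table
from traitboost.genes import (
    GeneModel,
    annotate_variants,
    candidate_genes,
    genotype_heatmap_order,
    read_gff3,
)

GFF_TEXT = """##gff-version 3
##sequence-region Chr1 1 20000
Chr1\tsyn\tgene\t1000\t2000\t.\t+\t.\tID=gplus
Chr1\tsyn\tmRNA\t1000\t2000\t.\t+\t.\tID=gplus.m;Parent=gplus
Chr1\tsyn\texon\t1000\t1300\t.\t+\t.\tParent=gplus.m
Chr1\tsyn\texon\t1700\t2000\t.\t+\t.\tParent=gplus.m
Chr1\tsyn\tCDS\t1100\t1300\t.\t+\t0\tParent=gplus.m
Chr1\tsyn\tCDS\t1700\t1900\t.\t+\t0\tParent=gplus.m
Chr1\tsyn\tgene\t5000\t6000\t.\t-\t.\tID=gminus
Chr1\tsyn\tmRNA\t5000\t6000\t.\t-\t.\tID=gminus.m;Parent=gminus
Chr1\tsyn\texon\t5000\t5300\t.\t-\t.\tParent=gminus.m
Chr1\tsyn\texon\t5700\t6000\t.\t-\t.\tParent=gminus.m
Chr1\tsyn\tCDS\t5100\t5300\t.\t-\t0\tParent=gminus.m
Chr1\tsyn\tCDS\t5700\t5900\t.\t-\t0\tParent=gminus.m
"""


@pytest.fixture(scope="module")
def genes(tmp_path_factory):
    path = tmp_path_factory.mktemp("gff") / "toy.gff3"
    path.write_text(GFF_TEXT)
    return read_gff3(path)


def variants_at(positions):
    return make_variant_table(
        ["Chr1"] * len(positions), positions, ["A"] * len(positions), ["T"] * len(positions)
    )


class TestReadGff3:
    def test_gene_models_loaded(self, genes):
        by_id = {g.gene_id: g for g in genes}
        assert set(by_id) == {"gplus", "gminus"}
        assert by_id["gplus"].strand == "+"
        assert by_id["gplus"].exons == [(1000, 1300), (1700, 2000)]
        assert by_id["gminus"].cds == [(5100, 5300), (5700, 5900)]


class TestRegionClassification:
    def test_all_seven_regions_on_plus_strand(self, genes):
        placements = {
            500: ("upstream", 500),
            1050: ("utr5", 0),
            1200: ("exon_cds", 0),
            1500: ("intron", 0),
            1800: ("exon_cds", 0),
            1950: ("utr3", 0),
            3000: ("downstream", 1000),
            15000: ("intergenic", None),
        }
        ann = annotate_variants(variants_at(list(placements)), genes, window=5000)
        for rec in ann.itertuples(index=False):
            pos = int(rec.variant_id.split("Pos")[1])
            region, dist = placements[pos]
            assert rec.region == region, pos
            if dist is not None and region in ("upstream", "downstream"):
                assert rec.distance == dist

    def test_strand_flip_on_minus_strand(self, genes):
        placements = {
            4800: "downstream",  # genomically left of a minus-strand gene
            5050: "utr3",
            5200: "exon_cds",
            5500: "intron",
            5950: "utr5",
            6400: "upstream",
        }
        ann = annotate_variants(variants_at(list(placements)), genes, window=5000)
        got = {
            int(r.variant_id.split("Pos")[1]): r.region
            for r in ann.itertuples(index=False)
        }
        assert got == placements

    def test_window_zero_gives_only_genic_or_intergenic(self, genes):
        ann = annotate_variants(variants_at([500, 1200, 3000, 5500]), genes, window=0)
        assert ann["region"].tolist() == ["intergenic", "exon_cds", "intergenic", "intron"]

    def test_every_variant_gets_exactly_one_region(self, genes):
        rng = np.random.default_rng(0)
        ann = annotate_variants(
            variants_at(sorted(rng.choice(np.arange(1, 20000), 300, replace=False))),
            genes,
            window=2000,
        )
        assert len(ann) == 300
        assert ann["region"].isin(
            ["exon_cds", "utr5", "utr3", "intron", "upstream", "downstream", "intergenic"]
        ).all()
        assert (ann["gene_id"].isna() == (ann["region"] == "intergenic")).all()

    def test_multi_gene_hit_reports_highest_priority(self):
        overlapping = [
            GeneModel("outer", "Chr1", 100, 1000, "+", exons=[(100, 1000)], cds=[]),
            GeneModel("inner", "Chr1", 400, 600, "+", exons=[(400, 600)], cds=[(400, 600)]),
        ]
        ann = annotate_variants(variants_at([500]), overlapping, window=0)
        assert ann.loc[0, "gene_id"] == "inner"
        assert ann.loc[0, "region"] == "exon_cds"

    def test_unknown_chromosome_warns_and_is_intergenic(self, genes):
        table = make_variant_table(["ChrX"], [100], ["A"], ["T"])
        with pytest.warns(UserWarning, match="unannotated"):
            ann = annotate_variants(table, genes)
        assert ann.loc[0, "region"] == "intergenic"


class TestCandidateGenes:
    def test_count_ordering_and_empty(self, genes):
        ann = annotate_variants(variants_at([1200, 1800, 5200, 15000]), genes, window=0)
        ranked = candidate_genes(ann)
        assert ranked["gene_id"].tolist() == ["gplus", "gminus"]
        assert ranked["n_variants"].tolist() == [2, 1]
        empty = candidate_genes(annotate_variants(variants_at([15000]), genes, window=0))
        assert empty.empty

    def test_truth_genes_recovered_on_synthetic_fixture(self, small_panel, fixture_dir):
        _, matrix, _, truth = small_panel
        models = read_gff3(fixture_dir["gff3"])
        causal = matrix.variants[
            matrix.variants["variant_id"].isin(truth.causal_variant_ids)
        ]
        ann = annotate_variants(causal, models, window=5000)
        ranked = candidate_genes(ann)
        hosted = set(ann["gene_id"].dropna())
        assert hosted <= set(ranked["gene_id"])


class TestHeatmapOrdering:
    def test_identical_accessions_cluster_adjacently(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, size=(6, 8)).astype(float)
        base[4] = base[0]  # duplicate accession within the same class
        labels = np.zeros(6, dtype=int)
        order = genotype_heatmap_order(base, labels)["row_order"]
        where = {r: i for i, r in enumerate(order)}
        assert abs(where[0] - where[4]) == 1

    def test_rows_grouped_by_phenotype_class(self):
        rng = np.random.default_rng(2)
        coded = rng.integers(-1, 3, size=(10, 5)).astype(float)
        labels = np.array([0, 1] * 5)
        order = genotype_heatmap_order(coded, labels)["row_order"]
        got_labels = labels[order]
        assert (got_labels[:5] == 0).all() and (got_labels[5:] == 1).all()

    def test_class_one_carries_more_alt_alleles_on_planted_fixture(self):
        cfg = tb.SimConfig(
            n_samples_per_pop=75, n_pops=2, n_variants=300, n_causal=10,
            effect_size=3.0, seed=21,
        )
        matrix, trait, truth = tb.simulate_study(cfg)
        y = trait["trait"].to_numpy()
        sub = matrix.subset_variants(truth.causal_variant_ids)
        coded = sub.to_heatmap_coding().astype(float)
        assert coded[y == 1].mean() > coded[y == 0].mean()

    def test_order_stable_under_row_permutation(self):
        rng = np.random.default_rng(3)
        # two well-separated blocks of accessions
        coded = np.vstack([np.zeros((4, 6)), np.full((4, 6), 2.0)])
        coded += rng.integers(0, 2, size=coded.shape) * 0.0
        labels = np.zeros(8, dtype=int)
        perm = rng.permutation(8)
        o1 = genotype_heatmap_order(coded, labels)["row_order"]
        o2 = genotype_heatmap_order(coded[perm], labels)["row_order"]
        # the two accession blocks stay contiguous either way
        def blocks(order, mapping):
            groups = [set(), set()]
            for i, row in enumerate(order):
                groups[0 if i < 4 else 1].add(mapping[row])
            return sorted(map(frozenset, groups), key=sorted)

        assert blocks(o1, list(range(8))) == blocks(o2, list(perm))

    def test_single_row_identity_order(self):
        out = genotype_heatmap_order(np.zeros((1, 4)), np.array([0]))
        assert out["row_order"].tolist() == [0]
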