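import numpy as np
import pytest

import traitboost as tb
from traitboost.datatypes import GenotypeMatrix, make_variant_table
from traitboost.f4 import (
    PopulationFrequencies,
    _weighted_jackknife_se,
    build_quartets,
    f4,
    population_frequencies,
)

from test_prune import matrix_from_dosage


def pf_from_freqs(freq, blocks=None):
    freq = np.asarray(freq, dtype=float)
    n_pops, n_var = freq.shape
    return PopulationFrequencies(
        populations=[f"P{i}" for i in range(n_pops)],
        freq=freq,
        counts=np.full_like(freq, 20.0),
        blocks=np.asarray(blocks if blocks is not None else np.arange(n_var)),
        variant_ids=[f"v{i}" for i in range(n_var)],
    )


class TestPopulationFrequencies:
    def test_hand_tallied_counts(self):
        # P0 = {s0,s1,s2}, P1 = {s3,s4,s5}
        dosage = np.array(
            [[1, 2], [0, 2], [np.nan, 2], [2, 0], [2, 1], [2, np.nan]], dtype=float
        )
        matrix = matrix_from_dosage(dosage)
        popmap = {f"s{i}": ("P0" if i < 3 else "P1") for i in range(6)}
        pf = population_frequencies(matrix, popmap, block_size=1)
        # variant 0: P0 has (1+0)/(2*2)=0.25, P1 has (2+2+2)/6=1.0
        assert pf.freq[0, 0] == pytest.approx(0.25)
        assert pf.freq[1, 0] == pytest.approx(1.0)
        # variant 1: P0 = 6/6 = 1.0, P1 = (0+1)/4 = 0.25
        assert pf.freq[0, 1] == pytest.approx(1.0)
        assert pf.freq[1, 1] == pytest.approx(0.25)

    def test_single_het_sample_gives_half(self):
        matrix = matrix_from_dosage(np.array([[1.0], [2.0]]))
        pf = population_frequencies(matrix, {"s0": "A", "s1": "B"}, block_size=1)
        assert pf.freq[0, 0] == pytest.approx(0.5)
        assert pf.freq[1, 0] == pytest.approx(1.0)

    def test_variant_with_uncalled_population_dropped(self):
        dosage = np.array([[1.0, np.nan], [2.0, 1.0]])
        matrix = matrix_from_dosage(dosage)
        pf = population_frequencies(matrix, {"s0": "A", "s1": "B"}, block_size=1)
        assert pf.variant_ids == [matrix.variant_ids[0]]

    def test_unmapped_sample_rejected(self):
        matrix = matrix_from_dosage(np.zeros((2, 1)))
        with pytest.raises(ValueError, match="missing from population map"):
            population_frequencies(matrix, {"s0": "A"})

    def test_blocks_are_contiguous_per_chromosome(self):
        dosage = np.tile([[0.0], [2.0]], (1, 10))
        variants = make_variant_table(
            ["Chr1"] * 6 + ["Chr2"] * 4,
            [10, 20, 30, 40, 50, 60, 10, 20, 30, 40],
            ["A"] * 10,
            ["T"] * 10,
        )
        matrix = GenotypeMatrix(samples=["s0", "s1"], variants=variants, dosage=dosage)
        pf = population_frequencies(matrix, {"s0": "A", "s1": "B"}, block_size=4)
        # Chr1: blocks 0,0,0,0,1,1 — Chr2 starts a fresh block: 2,2,2,2
        assert pf.blocks.tolist() == [0, 0, 0, 0, 1, 1, 2, 2, 2, 2]


class TestF4Statistic:
    def test_two_variant_worked_example(self):
        # (pA-pB)(pC-pD) per variant: (1-0)(1-0)=1 and (1-1)(0-0)=0 -> mean 0.5
        pf = pf_from_freqs([[1, 1], [0, 1], [1, 0], [0, 0]])
        res = f4(pf, ("P0", "P1", "P2", "P3"))
        assert res.f4 == pytest.approx(0.5)
        assert res.n_variants_used == 2

    def test_identical_sister_populations_give_exact_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, size=(3, 50))
        freq = np.vstack([p, p[2:3]])  # P3 == P2
        res = f4(pf_from_freqs(freq, blocks=np.arange(50) // 10), ("P0", "P1", "P2", "P3"))
        assert res.f4 == 0.0

    def test_exact_antisymmetries(self):
        rng = np.random.default_rng(1)
        freq = rng.uniform(0.05, 0.95, size=(4, 200))
        pf = pf_from_freqs(freq, blocks=np.arange(200) // 20)
        base = f4(pf, ("P0", "P1", "P2", "P3"))
        swap_cd = f4(pf, ("P0", "P1", "P3", "P2"))
        swap_ab = f4(pf, ("P1", "P0", "P2", "P3"))
        assert swap_cd.f4 == pytest.approx(-base.f4, abs=0)
        assert swap_ab.f4 == pytest.approx(-base.f4, abs=0)
        assert swap_cd.se == pytest.approx(base.se)
        assert swap_cd.p == pytest.approx(base.p)

    def test_f2_decomposition_route_agrees_with_product_route(self):
        rng = np.random.default_rng(2)
        freq = rng.uniform(0.0, 1.0, size=(4, 300))
        pf = pf_from_freqs(freq, blocks=np.arange(300) // 50)
        a = f4(pf, ("P0", "P1", "P2", "P3"), method="afprod")
        b = f4(pf, ("P0", "P1", "P2", "P3"), method="f2")
        assert a.f4 == pytest.approx(b.f4, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_duplicate_population_rejected(self):
        pf = pf_from_freqs(np.full((4, 4), 0.5))
        with pytest.raises(ValueError, match="distinct"):
            f4(pf, ("P0", "P0", "P2", "P3"))

    def test_fewer_than_two_blocks_rejected(self):
        pf = pf_from_freqs(np.random.default_rng(3).uniform(size=(4, 5)), blocks=[0] * 5)
        with pytest.raises(ValueError, match="blocks"):
            f4(pf, ("P0", "P1", "P2", "P3"))

    def test_interpretation_rule(self):
        cfg = tb.SimConfig(
            n_samples_per_pop=25, n_pops=4, n_variants=4000, n_causal=0,
            ld_block_size=1, missing_rate=0.0,
            admixture_events=((1, 3, 0.4),), seed=30,
        )
        _, freqs = tb.simulate_allele_frequencies(cfg)
        matrix, truth = tb.simulate_genotypes(freqs, cfg)
        pf = population_frequencies(matrix, truth.population_assignments, block_size=200)
        res = f4(pf, ("POP0", "POP1", "POP2", "POP3"))
        assert res.f4 > 0 and res.p < 0.05
        assert res.interpretation == "B-D flow"
        # flipped C/D: negative and read as B-C flow
        flipped = f4(pf, ("POP0", "POP1", "POP3", "POP2"))
        assert flipped.interpretation == "B-C flow"


class TestJackknife:
    def test_equal_blocks_reduce_to_classic_delete_one_jackknife(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=100)
        blocks = np.arange(100) // 10
        se = _weighted_jackknife_se(values, blocks)
        # classic delete-one-block jackknife with equal block sizes
        loo = np.array([values[blocks != b].mean() for b in range(10)])
        classic = np.sqrt((10 - 1) / 10 * ((loo - loo.mean()) ** 2).sum())
        assert se == pytest.approx(classic)

    def test_unequal_blocks_still_consistent(self):
        rng = np.random.default_rng(5)
        values = rng.normal(loc=0.3, size=90)
        blocks = np.repeat(np.arange(5), [10, 20, 30, 15, 15])
        se = _weighted_jackknife_se(values, blocks)
        naive = values.std(ddof=1) / np.sqrt(len(values))
        assert 0.3 * naive < se < 3.0 * naive  # same order as the iid SE


class TestBuildQuartets:
    COUNTRIES = [
        "STE", "IRA", "TUR", "GRE", "GEO", "MAC", "BEL", "US",
        "AFG", "IND", "CHI", "EGY", "ESP",
    ]
    HYPOTHESES = [
        ("IRA", "GRE", "TUR"), ("TUR", "MAC", "GRE"), ("IRA", "TUR", "GEO"),
        ("GEO", "GRE", "MAC"), ("BEL", "ESP", "US"), ("AFG", "CHI", "IND"),
        ("AFG", "IND", "CHI"), ("IND", "AFG", "CHI"), ("TUR", "GRE", "EGY"),
        ("EGY", "TUR", "ESP"),
    ]

    def test_outgroup_fills_a_position_for_every_hypothesis(self):
        quartets = build_quartets(self.COUNTRIES, "STE", self.HYPOTHESES)
        assert len(quartets) == 10
        assert all(q[0] == "STE" for q in quartets)
        assert quartets[0] == ("STE", "IRA", "GRE", "TUR")

    def test_empty_hypothesis_list(self):
        assert build_quartets(self.COUNTRIES, "STE", []) == []

    def test_duplicates_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            quartets = build_quartets(
                self.COUNTRIES, "STE", [("IRA", "GRE", "TUR")] * 2
            )
        assert len(quartets) == 1

    def test_unknown_population_rejected(self):
        with pytest.raises(ValueError, match="unknown population"):
            build_quartets(self.COUNTRIES, "STE", [("IRA", "XXX", "TUR")])
        with pytest.raises(ValueError, match="outgroup"):
            build_quartets(self.COUNTRIES, "ZZZ", [])
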