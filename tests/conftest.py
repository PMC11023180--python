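import numpy as np
import pandas as pd
import pytest

import traitboost as tb


@pytest.fixture(scope="session")
def small_panel():
    """120 samples x 400 variants, 5 causal at strong effect, 4 populations."""
    cfg = tb.SimConfig(
        n_samples_per_pop=30,
        n_pops=4,
        n_variants=400,
        n_causal=5,
        effect_size=2.0,
        seed=11,
    )
    matrix, traits, truth = tb.simulate_study(cfg)
    return cfg, matrix, traits, truth


@pytest.fixture(scope="session")
def fixture_dir(small_panel, tmp_path_factory):
    cfg, matrix, traits, truth = small_panel
    out = tmp_path_factory.mktemp("fixture")
    paths = tb.write_fixture(matrix, traits, truth, cfg, out)
    return paths


def write_vcf(path, records, samples=("S0", "S1", "S2")):
    """Write a minimal VCF; records are (chrom, pos, ref, alt, info, gts)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=Chr1,length=1000000>\n")
        fh.write("##contig=<ID=Chr2,length=1000000>\n")
        for key in tb.datatypes.INFO_METRICS:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="x">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, ref, alt, info, gts in records:
            info_s = (
                ";".join(f"{k}={v}" for k, v in info.items()) if info else "."
            )
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info_s}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path


PASSING_INFO = {
    "AC": 20,
    "MQ": 50.0,
    "DP": 5000,
    "SOR": 1.0,
    "QD": 15.0,
    "FS": 5.0,
    "MQRankSum": 0.0,
    "ReadPosRankSum": 0.0,
    "BaseQRankSum": 0.0,
}
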