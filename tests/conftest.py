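import numpy as np
import pandas as pd
import pytest

from txevo import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    cfg = sim.CohortConfig(n_tumours=3, regions_per_tumour=(2, 3), n_genes=60,
                           snps_per_gene=(1, 2), purity_range=(0.4, 0.8),
                           seed=123)
    return sim.generate_cohort(cfg)


def _variant(pos, **kw):
    base = dict(chrom="tx1", pos=pos, ref="A", alt="G", transcript_strand="+",
                context5="ACGT", context3="TGCA", up="T", down="T",
                rna_depth=50, rna_alt=10, dna_germline_depth=40,
                dna_tumour_depth_total=100, dna_alt_support=0,
                dna_error_support=0, region_id="T000_R1", tumour_id="T000")
    base.update(kw)
    return base


@pytest.fixture(scope="session")
def toy_variant_table():
    """Twelve hand-constructed candidate variants: five clean survivors and
    seven decoys, each built to fail exactly one filter rule."""
    rows = [
        _variant(10),
        _variant(20, ref="C", alt="T", context5="GATC", context3="ATCG",
                 up="C", down="A"),
        _variant(30, rna_depth=300, rna_alt=3),            # VAF exactly 1%
        _variant(40, transcript_strand="-"),
        _variant(50, rna_depth=12, rna_alt=12),
        _variant(60, dna_germline_depth=29),               # low_germline_dna
        _variant(70, dna_tumour_depth_total=29),           # low_tumour_dna
        _variant(80, rna_depth=9, rna_alt=3),              # low_rna_coverage
        _variant(90, rna_depth=50, rna_alt=2),             # low_alt_support
        _variant(100, rna_depth=1000, rna_alt=9),          # low_vaf (0.9%)
        _variant(110, dna_tumour_depth_total=200,
                 dna_alt_support=8, dna_error_support=0),  # dna_support
        _variant(120, context5="AAAA"),                    # homopolymer_flank
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def toy_vcf(toy_variant_table, tmp_path_factory):
    from txevo import io as io_mod
    path = tmp_path_factory.mktemp("vcf") / "toy.vcf"
    io_mod.write_variants_vcf(toy_variant_table, path, {"tx1": 2000})
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
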