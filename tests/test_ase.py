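"""ASE framework: per-SNP tests, independent filter, Fisher combination,
classification rules and downstream summaries."""

import numpy as np
import pandas as pd
import pytest

from oracles import betabin_tail_oracle
from txevo import ase


def make_snps(rows):
    base = dict(snp_id="s", gene_id="g1", tumour_id="T1", region_id="R1",
                chrom="chr1", pos=100, phase_block_id="g1",
                dna_major_count=60, dna_minor_count=40,
                rna_major_count=30, rna_minor_count=20,
                major_cn=1, minor_cn=1, major_is_reference=True,
                major_is_hap1=True)
    out = []
    for i, r in enumerate(rows):
        d = dict(base)
        d.update(snp_id=f"s{i}", pos=100 + i, **r)
        out.append(d)
    return pd.DataFrame(out)


class TestIndependentFilter:
    @pytest.mark.parametrize("t, cpn, keep", [
        (10, 0.5, True),    # 0.5**10 = 0.0009765625 < 0.001
        (9, 0.5, False),    # 0.5**9 = 0.001953125
        (20, 0.9, False),   # 0.9**20 ~ 0.1216
    ])
    def test_boundaries(self, t, cpn, keep):
        assert ase.independent_filter(t, cpn) is keep

    def test_vectorised(self):
        got = ase.independent_filter([10, 9], [0.5, 0.5])
        assert got.tolist() == [True, False]


class TestSnpTests:
    def test_binomial_closed_form(self):
        snps = make_snps([dict(rna_major_count=5, rna_minor_count=5)])
        res = ase.test_snps(snps, rho=0.0)
        assert res.loc[0, "p_eq1"] == pytest.approx(0.623046875, abs=1e-12)

    def test_all_three_tails_against_oracle(self):
        snps = make_snps([dict(rna_major_count=10, rna_minor_count=0,
                               major_cn=2, minor_cn=1)])
        res = ase.test_snps(snps, rho=0.05).iloc[0]
        assert res["p_eq1"] == pytest.approx(
            betabin_tail_oracle(10, 10, 0.5, 0.05), abs=1e-12)
        assert res["p_eq3"] == pytest.approx(
            1.0 - betabin_tail_oracle(10, 10, 0.5, 0.05), abs=1e-12)
        assert res["p_eq4"] == pytest.approx(
            betabin_tail_oracle(10, 10, 2 / 3, 0.05), abs=1e-12)

    def test_coverage_threshold_is_strict(self):
        snps = make_snps([dict(rna_major_count=4, rna_minor_count=4),
                          dict(rna_major_count=5, rna_minor_count=4)])
        res = ase.test_snps(snps)
        assert not res.loc[0, "evaluable"]   # t = 8 is not > 8
        assert res.loc[1, "evaluable"]

    def test_loh_sites_removed(self):
        snps = make_snps([
            dict(rna_major_count=30, rna_minor_count=5, major_cn=2, minor_cn=0),
            dict(rna_major_count=30, rna_minor_count=5, major_cn=0, minor_cn=2),
        ])
        res = ase.test_snps(snps)
        assert not res["passes_independent_filter"].any()


class TestCombination:
    def test_fisher_identities(self):
        assert ase.fisher_combine([0.5]) == pytest.approx(0.5, abs=1e-12)
        assert ase.fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_fisher_oracle(self):
        # chi2 = -2(ln 0.01 + ln 0.02) = 17.034..., df = 4
        assert ase.fisher_combine([0.01, 0.02]) == pytest.approx(
            0.0019034386382832487, abs=1e-12)

    def test_zero_usable_snps_not_evaluable(self):
        snps = make_snps([dict(rna_major_count=4, rna_minor_count=4)])
        gene = ase.combine_genes(ase.test_snps(snps))
        assert gene.loc[0, "n_snps_used"] == 0
        labelled = ase.classify_cohort(gene)
        assert labelled.loc[0, "label"] == "not_evaluable"


class TestClassification:
    def test_label_rules(self):
        gene_results = pd.DataFrame({
            "tumour_id": "T1", "region_id": "R1",
            "gene_id": ["a", "b", "c"], "n_snps_used": 1,
            "p_combined_A": [1e-8, 0.9, 0.5],
            "p_combined_B": [0.9, 1e-8, 0.5],
        })
        labelled = ase.classify_cohort(gene_results)
        got = labelled.set_index("gene_id")["label"]
        assert got["a"] == "cn_dependent_ase"
        assert got["b"] == "cn_independent_ase"
        assert got["c"] == "biallelic"

    def test_labels_partition_evaluable_genes(self):
        rng = np.random.default_rng(5)
        gene_results = pd.DataFrame({
            "tumour_id": "T1", "region_id": "R1",
            "gene_id": [f"g{i}" for i in range(50)],
            "n_snps_used": 1,
            "p_combined_A": rng.uniform(size=50),
            "p_combined_B": rng.uniform(size=50),
        })
        labelled = ase.classify_cohort(gene_results)
        assert set(labelled["label"]) <= {"biallelic", "cn_dependent_ase",
                                          "cn_independent_ase"}
        assert labelled["label"].notna().all()

    def test_empty_input(self):
        empty = ase.classify_cohort(pd.DataFrame(
            columns=["tumour_id", "region_id", "gene_id", "n_snps_used",
                     "p_combined_A", "p_combined_B"]))
        assert len(empty) == 0


class TestEnrichment:
    def test_symmetric_table(self):
        res = ase.odds_ratio_from_table([[5, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_cross_product(self):
        res = ase.odds_ratio_from_table([[10, 90], [1, 899]])
        assert res.odds_ratio == pytest.approx(10 * 899 / 90, rel=1e-12)

    def test_one_sided_hypergeometric(self):
        res = ase.odds_ratio_from_table([[10, 0], [0, 10]],
                                        alternative="greater")
        # exact enumeration: P = 1 / C(20, 10)
        from scipy.special import comb
        assert res.pvalue == pytest.approx(1 / comb(20, 10, exact=True))

    def test_degenerate_margin_flagged(self):
        res = ase.odds_ratio_from_table([[0, 0], [3, 4]])
        assert not res.defined

    def test_series_interface(self):
        labels = pd.Series([True] * 4 + [False] * 6,
                           index=[f"g{i}" for i in range(10)])
        annot = pd.Series([True, True, False, False] + [False] * 6,
                          index=labels.index)
        res = ase.enrichment_odds_ratio(labels, annot)
        assert res.table.tolist() == [[2, 2], [0, 6]]


class TestIth:
    def _labels(self, spec):
        rows = []
        for gene, per_region in spec.items():
            for region, lab in per_region.items():
                rows.append((gene, region, lab))
        return pd.DataFrame(rows, columns=["gene_id", "region_id", "label"])

    def test_fully_homogeneous(self):
        labels = self._labels({
            "a": {"R1": "cn_independent_ase", "R2": "cn_independent_ase"}})
        assert ase.cn_indep_ase_ith(labels) == 0.0

    def test_fully_heterogeneous_denominator(self):
        labels = self._labels({
            "a": {"R1": "cn_independent_ase", "R2": "cn_independent_ase",
                  "R3": "biallelic"}})
        assert ase.cn_indep_ase_ith(labels) == 1.0

    def test_half(self):
        spec = {}
        for g in ("a", "b"):  # homogeneous in both regions
            spec[g] = {"R1": "cn_independent_ase", "R2": "cn_independent_ase"}
        for g in ("c", "d"):  # seen in 2 of 3 evaluable regions
            spec[g] = {"R1": "cn_independent_ase", "R2": "cn_independent_ase",
                       "R3": "biallelic"}
        assert ase.cn_indep_ase_ith(self._labels(spec)) == 0.5

    def test_no_qualifying_gene(self):
        labels = self._labels({"a": {"R1": "cn_independent_ase",
                                     "R2": "biallelic"}})
        assert np.isnan(ase.cn_indep_ase_ith(labels))


class TestReferenceBias:
    @pytest.mark.parametrize("ref, alt, expected", [
        (10, 10, 1.0), (15, 5, 3.0)])
    def test_ratio(self, ref, alt, expected):
        assert ase.reference_bias(ref, alt) == expected

    def test_zero_denominator_flagged(self):
        assert np.isinf(ase.reference_bias(4, 0))


class TestPromoterAsm:
    def _cpgs(self, triples):
        return pd.DataFrame(triples, columns=["position", "m_t_point",
                                              "hdi99_low", "hdi99_high"])

    def test_three_consecutive(self):
        cpgs = self._cpgs([(i, 0.5, 0.3, 0.6) for i in range(3)])
        assert ase.classify_promoter_asm(cpgs)

    def test_two_only(self):
        cpgs = self._cpgs([(0, 0.5, 0.3, 0.6), (1, 0.5, 0.3, 0.6),
                           (2, 0.9, 0.8, 0.95)])
        assert not ase.classify_promoter_asm(cpgs)

    def test_broken_run(self):
        cpgs = self._cpgs([(0, 0.5, 0.3, 0.6), (1, 0.1, 0.05, 0.2),
                           (2, 0.5, 0.3, 0.6), (3, 0.5, 0.3, 0.6)])
        assert not ase.classify_promoter_asm(cpgs)

    def test_hdi_rule(self):
        # point in range but interval too wide -> not an ASM locus
        assert not ase.is_asm_locus(0.5, 0.1, 0.6)
        assert ase.is_asm_locus(0.5, 0.15, 0.75)


class TestMsai:
    def _snps(self, rows):
        return make_snps(rows)

    def test_genomic_msai(self):
        # region 1: hap1 strongly amplified in DNA; region 2: hap2
        snps = self._snps([
            dict(region_id="R1", dna_major_count=90, dna_minor_count=10,
                 major_is_hap1=True, rna_major_count=40, rna_minor_count=10),
            dict(region_id="R2", dna_major_count=90, dna_minor_count=10,
                 major_is_hap1=False, rna_major_count=40, rna_minor_count=10),
        ])
        res = ase.test_snps(snps)
        gene = ase.classify_cohort(ase.combine_genes(res))
        events = ase.detect_msai(res, gene)
        assert (events["event_type"] == "genomic").any()

    def test_genomic_transcriptomic_msai(self):
        # regions 1-2: LOH of hap2 (hap1 DNA-major, imbalanced); region 3:
        # balanced DNA but CN-independent ASE favouring hap2
        rows = []
        for r in ("R1", "R2"):
            rows.append(dict(region_id=r, dna_major_count=95,
                             dna_minor_count=5, major_is_hap1=True,
                             major_cn=2, minor_cn=0,
                             rna_major_count=45, rna_minor_count=5))
        rows.append(dict(region_id="R3", dna_major_count=50,
                         dna_minor_count=50, major_is_hap1=False,
                         major_cn=1, minor_cn=1,
                         rna_major_count=48, rna_minor_count=2))
        res = ase.test_snps(self._snps(rows))
        gene = ase.classify_cohort(ase.combine_genes(res))
        # region 3's major (hap2) is overexpressed way beyond its CN
        assert gene.set_index("region_id").loc["R3", "label"] \
            == "cn_independent_ase"
        events = ase.detect_msai(res, gene)
        gt = events[events["event_type"] == "genomic_transcriptomic"]
        assert len(gt) >= 1
        assert (gt["region_1"] == "R3").all()

    def test_single_region_no_events(self):
        snps = self._snps([dict(region_id="R1", dna_major_count=90,
                                dna_minor_count=10)])
        res = ase.test_snps(snps)
        gene = ase.classify_cohort(ase.combine_genes(res))
        assert len(ase.detect_msai(res, gene)) == 0

    def test_unphased_gene_skipped(self, caplog):
        snps = self._snps([
            dict(region_id="R1", dna_major_count=90, dna_minor_count=10,
                 phase_block_id=np.nan),
            dict(region_id="R2", dna_major_count=90, dna_minor_count=10,
                 phase_block_id=np.nan, major_is_hap1=False),
        ])
        res = ase.test_snps(snps)
        gene = ase.classify_cohort(ase.combine_genes(res))
        import logging
        with caplog.at_level(logging.INFO, logger="txevo.ase"):
            events = ase.detect_msai(res, gene)
        assert len(events) == 0
        assert "unphased" in caplog.text
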