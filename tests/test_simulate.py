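"""Synthetic-data generators: determinism, truth bookkeeping, count models
and round-tripping through the pipeline readers."""

import numpy as np
import pandas as pd
import pytest

from txevo import io as io_mod
from txevo import simulate as sim
from txevo.pipeline import default_signature_truth
from txevo.variants import filter_variants


class TestCohortScaffold:
    def test_seeded_determinism(self):
        cfg = sim.CohortConfig(seed=9)
        a = sim.generate_cohort(cfg)
        b = sim.generate_cohort(sim.CohortConfig(seed=9))
        pd.testing.assert_frame_equal(a.regions, b.regions)
        pd.testing.assert_frame_equal(a.copy_number, b.copy_number)

    def test_degenerate_purity_interval(self):
        cfg = sim.CohortConfig(purity_range=(1.0, 1.0), seed=1)
        cohort = sim.generate_cohort(cfg)
        assert (cohort.regions["purity"] == 1.0).all()

    def test_bookkeeping(self):
        cfg = sim.CohortConfig(n_tumours=5, regions_per_tumour=3,
                               n_genes=200, seed=2)
        cohort = sim.generate_cohort(cfg)
        assert len(cohort.regions) == 15
        per_tumour = cohort.copy_number.groupby("tumour_id").size()
        assert (per_tumour == 200).all()

    def test_cn_states_valid(self, small_cohort):
        cn = small_cohort.copy_number
        assert (cn["major_cn"] >= cn["minor_cn"]).all()
        assert (cn["minor_cn"] >= 0).all()
        assert ((cn["major_cn"] + cn["minor_cn"]) > 0).all()

    @pytest.mark.parametrize("kw", [
        dict(purity_range=(0.0, 0.5)), dict(rna_overdispersion=1.0),
        dict(n_tumours=0), dict(snps_per_gene=(3, 1))])
    def test_invalid_config(self, kw):
        with pytest.raises(sim.ConfigurationError):
            sim.CohortConfig(**kw)


class TestAseCounts:
    def test_null_config_has_no_ase_genes(self, small_cohort):
        cfg = sim.AseTruthConfig(frac_cn_indep_ase=0, frac_imprinted=0,
                                 frac_truncating_nmd=0)
        _, truth = sim.simulate_ase_counts(small_cohort, cfg)
        assert (truth["true_class"] != "cn_indep").all()
        balanced = small_cohort.copy_number.query("major_cn == minor_cn")
        merged = truth.merge(balanced, on=["tumour_id", "gene_id"])
        assert (merged["true_class"] == "none").all()

    def test_truth_is_exhaustive_and_fractions_respected(self, small_cohort):
        cfg = sim.AseTruthConfig(frac_cn_indep_ase=0.1)
        _, truth = sim.simulate_ase_counts(small_cohort, cfg)
        n_genes = len(small_cohort.genes)
        assert len(truth) == n_genes * small_cohort.config.n_tumours
        per_tumour = truth[truth["true_class"] == "cn_indep"] \
            .groupby("tumour_id").size()
        assert (per_tumour == round(0.1 * n_genes)).all()

    def test_sigma_zero_counts_are_binomial(self):
        # empirical variance over 1e4 draws matches t p (1-p)
        rng = np.random.default_rng(0)
        t, q = 20, 0.3
        draws = np.array([sim._betabin_draw(rng, q, t, 0.0)
                          for _ in range(10_000)])
        expected_var = t * q * (1 - q)
        assert np.var(draws) == pytest.approx(expected_var, rel=0.05)
        assert np.mean(draws) == pytest.approx(t * q, rel=0.02)

    def test_sigma_inflates_variance(self):
        rng = np.random.default_rng(0)
        t, q, sigma = 50, 0.5, 0.1
        draws = np.array([sim._betabin_draw(rng, q, t, sigma)
                          for _ in range(10_000)])
        inflation = 1 + (t - 1) * sigma
        assert np.var(draws) == pytest.approx(
            t * q * (1 - q) * inflation, rel=0.1)

    def test_deterministic_and_round_trips(self, small_cohort, tmp_path):
        cfg = sim.AseTruthConfig()
        a, _ = sim.simulate_ase_counts(small_cohort, cfg)
        b, _ = sim.simulate_ase_counts(small_cohort, cfg)
        pd.testing.assert_frame_equal(a, b)
        path = tmp_path / "snps.tsv"
        io_mod.write_snp_table(a, path)
        back = io_mod.read_snp_table(path)
        pd.testing.assert_frame_equal(
            back, a[back.columns].reset_index(drop=True))

    def test_depth_validation(self, small_cohort):
        with pytest.raises(sim.ConfigurationError):
            sim.simulate_ase_counts(small_cohort, sim.AseTruthConfig(),
                                    depth_mean=0)


class TestExpression:
    def test_dimensions_and_determinism(self, small_cohort):
        counts, truth = sim.simulate_expression(small_cohort)
        assert counts.shape == (len(small_cohort.genes),
                                len(small_cohort.regions))
        counts2, _ = sim.simulate_expression(small_cohort)
        pd.testing.assert_frame_equal(counts, counts2)

    def test_within_tumour_more_correlated_than_between(self, small_cohort):
        counts, _ = sim.simulate_expression(small_cohort)
        log = np.log1p(counts)
        corr = log.corr()
        mapping = small_cohort.regions.set_index("region_id")["tumour_id"]
        within, between = [], []
        cols = list(counts.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                (within if mapping[a] == mapping[b] else between).append(
                    corr.loc[a, b])
        assert np.mean(within) > np.mean(between)

    def test_zero_perturbation_gives_near_identical_regions(self):
        cfg = sim.CohortConfig(n_tumours=2, regions_per_tumour=2,
                               n_genes=150, seed=4)
        cohort = sim.generate_cohort(cfg)
        counts, _ = sim.simulate_expression(
            cohort, sim.ExpressionConfig(region_sigma=0.0, nb_size=200.0))
        from txevo.expression import ited
        mapping = cohort.regions.set_index("region_id")["tumour_id"]
        res = ited(counts, mapping, n_top=100)
        assert res["ited_region"].max() < 0.05


@pytest.fixture(scope="module")
def tx():
    return sim.synthetic_transcriptome(n_transcripts=10, length=1500, seed=5)


class TestRnaVariants:
    def test_point_mass_exposure_hits_single_channel(self, tx):
        from txevo.signatures import CHANNEL_INDEX
        cfg = sim.CohortConfig(n_tumours=1, regions_per_tumour=1, seed=5)
        cohort = sim.generate_cohort(cfg)
        S = np.zeros((192, 2))
        S[CHANNEL_INDEX["T[A>G]C"], 0] = 1.0
        S[CHANNEL_INDEX["C[C>T]G"], 1] = 1.0
        truth = sim.SignatureTruth(S, np.array([[1.0, 0.0]]),
                                   variants_per_region=40)
        variants, _ = sim.simulate_rna_variants(cohort, truth, tx)
        assert (variants["truth_channel"] == "T[A>G]C").all()

    def test_no_decoys_all_pass(self, tx):
        cfg = sim.CohortConfig(n_tumours=1, regions_per_tumour=2, seed=6)
        cohort = sim.generate_cohort(cfg)
        truth = default_signature_truth(2, 60, seed=6)
        variants, _ = sim.simulate_rna_variants(cohort, truth, tx)
        filtered = filter_variants(variants)
        assert filtered["passes"].all()

    def test_decoys_fail_exactly_their_rule(self, tx):
        cfg = sim.CohortConfig(n_tumours=1, regions_per_tumour=1, seed=7)
        cohort = sim.generate_cohort(cfg)
        truth = default_signature_truth(1, 50, seed=7)
        fractions = {rule: 0.1 for rule in sim._DECOY_RULES}
        blacklist = sim.default_blacklist(tx)
        variants, _ = sim.simulate_rna_variants(
            cohort, truth, tx, decoy_fractions=fractions, blacklist=blacklist)
        filtered = filter_variants(variants, blacklist=blacklist)
        decoys = filtered[filtered["is_decoy"]]
        assert len(decoys) == 8 * 5
        assert (decoys["flags"] == decoys["decoy_rule"]).all()
        assert filtered[~filtered["is_decoy"]]["passes"].all()

    def test_missing_context_names_channel(self):
        tiny = sim.Transcriptome([("t1", "A" * 60, "+")])
        cfg = sim.CohortConfig(n_tumours=1, regions_per_tumour=1, seed=8)
        cohort = sim.generate_cohort(cfg)
        S = np.zeros((192, 1))
        from txevo.signatures import CHANNEL_INDEX
        S[CHANNEL_INDEX["C[C>T]G"], 0] = 1.0
        truth = sim.SignatureTruth(S, np.array([[1.0]]), 5)
        with pytest.raises(sim.GenerationError, match=r"C\[C>T\]G"):
            sim.simulate_rna_variants(cohort, truth, tiny)

    def test_vcf_round_trip(self, tx, tmp_path):
        cfg = sim.CohortConfig(n_tumours=1, regions_per_tumour=1, seed=9)
        cohort = sim.generate_cohort(cfg)
        truth = default_signature_truth(1, 30, seed=9)
        variants, _ = sim.simulate_rna_variants(cohort, truth, tx)
        path = tmp_path / "cand.vcf"
        io_mod.write_variants_vcf(variants, path,
                                  {n: len(s) for n, s, _ in tx.records})
        back = io_mod.read_variants_vcf(path)
        assert len(back) == len(variants)
        key = ["chrom", "pos", "ref", "alt"]
        a = variants.sort_values(key).reset_index(drop=True)
        b = back.sort_values(key).reset_index(drop=True)
        for col in ["chrom", "pos", "ref", "alt", "transcript_strand",
                    "context5", "context3", "rna_depth", "rna_alt",
                    "dna_germline_depth", "region_id"]:
            assert (a[col] == b[col]).all(), col

    def test_fasta_and_strand_round_trip(self, tx, tmp_path):
        fa = tmp_path / "tx.fa"
        io_mod.write_fasta([(n, s) for n, s, _ in tx.records], fa)
        seqs = io_mod.read_fasta(fa)
        assert seqs == tx.sequences()
        st = tmp_path / "strands.tsv"
        io_mod.write_strand_table(tx.strands(), st)
        pd.testing.assert_frame_equal(io_mod.read_strand_table(st),
                                      tx.strands())
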