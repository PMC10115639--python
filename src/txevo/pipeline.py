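"""End-to-end orchestration: simulate -> ASE -> expression -> RNA stages.

A single YAML-style configuration dict drives all stages; every threshold
defaults to the analysis defaults (sigma = 0.05, FDR 0.05, the variant
filter cut-offs, 500 variable genes, 0.001 transcript-fraction grid step)
and any override is logged.  All randomness is funnelled through one seed,
from which each stage derives its own generator, so a rerun with the same
configuration produces byte-identical artefacts; the run report lists every
output with a checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import expression as expr_mod
from . import io as io_mod
from . import motif as motif_mod
from . import signatures as sig_mod
from . import simulate as sim_mod
from . import variants as var_mod

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "txevo_out",
    "stages": {"simulate": True, "ase": True, "expression": True, "rna": True},
    "cohort": {"n_tumours": 6, "regions_per_tumour": [2, 3], "n_genes": 150,
               "snps_per_gene": [1, 3], "purity_range": [0.3, 0.8],
               "rna_overdispersion": 0.05},
    "ase_truth": {"frac_cn_indep_ase": 0.05, "frac_imprinted": 0.02,
                  "frac_truncating_nmd": 0.02, "ase_allelic_ratio": 0.9},
    "ase": {"rho": 0.05, "fdr": 0.05},
    "expression": {"n_top": 500},
    "rna": {"n_signatures": 2, "variants_per_region": 120,
            "decoy_fractions": {"low_rna_coverage": 0.05,
                                "low_alt_support": 0.05,
                                "homopolymer_flank": 0.05,
                                "blacklist": 0.05}},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            if key in base and base[key] != val:
                logger.info("config override: %s = %r (default %r)",
                            key, val, base[key])
            out[key] = val
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_signature_truth(n_regions: int, variants_per_region: int,
                            seed: int, k: int = 2) -> sim_mod.SignatureTruth:
    """Two synthetic signatures in the spirit of the observed RNA editing
    processes: one concentrated on A>G channels (ADAR-like) and one on C>T
    channels at CAT context (APOBEC3A-like), with smooth region-to-region
    exposure variation."""
    rng = np.random.default_rng([seed % (2 ** 31), 97])
    S = np.zeros((sig_mod.N_CHANNELS, k))
    for j, (ref, alt, pref_up) in enumerate(
            [("A", "G", None), ("C", "T", "T"), ("G", "A", None),
             ("T", "C", None)][:k]):
        for i, ch in enumerate(sig_mod.CHANNELS):
            up, r, a, down = sig_mod.parse_channel(ch)
            if (r, a) == (ref, alt):
                S[i, j] = 3.0 if pref_up and up == pref_up else 1.0
        S[:, j] /= S[:, j].sum()
    E = rng.dirichlet(np.ones(k) * 2.0, size=n_regions)
    return sim_mod.SignatureTruth(S, E, variants_per_region)


def run(config: dict | None = None) -> dict:
    """Run the configured stages; returns the run report (also written to
    ``<outdir>/manifest.json``)."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])
    outdir = io_mod.ensure_dir(cfg["outdir"])
    report: dict = {"seed": seed, "stages": {}, "artefacts": {}}

    def save(name: str, writer, *args) -> Path:
        path = outdir / name
        writer(*args, path)
        report["artefacts"][name] = _sha256(path)
        return path

    ccfg = cfg["cohort"]
    cohort_config = sim_mod.CohortConfig(
        n_tumours=ccfg["n_tumours"],
        regions_per_tumour=tuple(np.atleast_1d(ccfg["regions_per_tumour"])),
        n_genes=ccfg["n_genes"],
        snps_per_gene=tuple(np.atleast_1d(ccfg["snps_per_gene"])),
        purity_range=tuple(ccfg["purity_range"]),
        rna_overdispersion=ccfg["rna_overdispersion"], seed=seed)
    cohort = sim_mod.generate_cohort(cohort_config)
    logger.info("cohort: %d tumours, %d regions, %d genes",
                cohort_config.n_tumours, len(cohort.regions),
                cohort_config.n_genes)

    stages = cfg["stages"]
    snps = counts = variants = None
    if stages.get("simulate", True):
        ase_cfg = sim_mod.AseTruthConfig(**cfg["ase_truth"])
        snps, ase_truth = sim_mod.simulate_ase_counts(cohort, ase_cfg)
        counts, _ = sim_mod.simulate_expression(cohort)
        tx = sim_mod.synthetic_transcriptome(seed=seed)
        blacklist = sim_mod.default_blacklist(tx)
        sig_truth = default_signature_truth(
            len(cohort.regions), cfg["rna"]["variants_per_region"], seed,
            cfg["rna"]["n_signatures"])
        variants, exposure_truth = sim_mod.simulate_rna_variants(
            cohort, sig_truth, tx,
            decoy_fractions=cfg["rna"]["decoy_fractions"], blacklist=blacklist)
        save("snp_counts.tsv", io_mod.write_snp_table, snps)
        save("ase_truth.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False),
             ase_truth)
        save("expression_counts.tsv", io_mod.write_counts, counts)
        save("region_meta.tsv", io_mod.write_region_meta, cohort.regions)
        save("transcriptome.fa", io_mod.write_fasta,
             [(n, s) for n, s, _ in tx.records])
        save("transcript_strands.tsv", io_mod.write_strand_table, tx.strands())
        save("blacklist.bed", io_mod.write_bed, blacklist)
        save("candidates.vcf",
             lambda df, p: io_mod.write_variants_vcf(
                 df, p, {n: len(s) for n, s, _ in tx.records}), variants)
        save("exposure_truth.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), exposure_truth)
        report["stages"]["simulate"] = {
            "n_snps": len(snps), "n_variants": len(variants),
            "n_regions": len(cohort.regions)}
    if stages.get("ase", True):
        if snps is None:
            path = outdir / "snp_counts.tsv"
            if not path.exists():
                raise FileNotFoundError(
                    "ase stage requires snp_counts.tsv (enable simulate or "
                    "provide inputs)")
            snps = io_mod.read_snp_table(path)
        snp_res, gene_res = ase_mod.run_ase(
            snps, rho=cfg["ase"]["rho"], alpha=cfg["ase"]["fdr"])
        save("ase_genes.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), gene_res)
        msai = ase_mod.detect_msai(snp_res, gene_res)
        save("msai_events.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), msai)
        labelled = gene_res[gene_res["label"] != "not_evaluable"]
        report["stages"]["ase"] = {
            "n_gene_tests": len(labelled),
            "n_cn_dependent": int((labelled["label"] == "cn_dependent_ase").sum()),
            "n_cn_independent": int((labelled["label"] == "cn_independent_ase").sum()),
            "n_msai_events": len(msai)}
    if stages.get("expression", True):
        if counts is None:
            path = outdir / "expression_counts.tsv"
            if not path.exists():
                raise FileNotFoundError("expression stage requires "
                                        "expression_counts.tsv")
            counts = io_mod.read_counts(path)
        region_to_tumour = cohort.regions.set_index("region_id")["tumour_id"]
        ited_res = expr_mod.ited(counts, region_to_tumour,
                                 n_top=cfg["expression"]["n_top"])
        save("ited.tsv", lambda df, p: df.to_csv(p, sep="\t", index=False),
             ited_res)
        # transcript fraction per region from the simulated SNP counts
        tf_rows = []
        if snps is not None:
            for region, sub in snps.groupby("region_id", sort=False):
                tot = sub["rna_major_count"] + sub["rna_minor_count"]
                baf_df = pd.DataFrame({
                    "baf": sub["rna_major_count"] / tot.clip(lower=1),
                    "major_cn": sub["major_cn"], "minor_cn": sub["minor_cn"]})
                fit = expr_mod.estimate_transcript_fraction(baf_df)
                tf_rows.append((region, fit.rho_rna, fit.fit_loss,
                                fit.identifiable, fit.n_snps))
        tf = pd.DataFrame(tf_rows, columns=["region_id", "rho_rna", "fit_loss",
                                            "identifiable", "n_snps"])
        save("transcript_fraction.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), tf)
        report["stages"]["expression"] = {
            "n_tumours_with_ited": int(ited_res["ited_tumour"].notna()
                                       .groupby(ited_res["tumour_id"]).any().sum()),
            "n_transcript_fraction_fits": len(tf)}
    if stages.get("rna", True):
        if variants is None:
            path = outdir / "candidates.vcf"
            if not path.exists():
                raise FileNotFoundError("rna stage requires candidates.vcf")
            variants = io_mod.read_variants_vcf(path)
        blacklist = io_mod.read_bed(outdir / "blacklist.bed") \
            if (outdir / "blacklist.bed").exists() else None
        filtered = var_mod.filter_variants(variants, blacklist=blacklist)
        save("variants_filtered.tsv",
             lambda df, p: df.to_csv(p, sep="\t", index=False), filtered)
        passed = filtered[filtered["passes"]]
        spectra, exposures = {}, {}
        k = cfg["rna"]["n_signatures"]
        sigs = default_signature_truth(1, 1, seed, k).signature_matrix
        for region, sub in passed.groupby("region_id", sort=False):
            spec = sig_mod.build_spectrum(sub)
            spectra[region] = spec
            fit = sig_mod.fit_exposures(spec, sigs)
            if fit.eligible:
                exposures[region] = fit.weights
        spec_df = pd.DataFrame(spectra)
        spec_df.index.name = "channel"
        save("spectra.tsv", lambda df, p: df.to_csv(p, sep="\t"), spec_df)
        exp_df = pd.DataFrame(exposures).T
        exp_df.columns = [f"sig{j + 1}" for j in range(k)]
        exp_df.index.name = "region_id"
        save("exposures.tsv", lambda df, p: df.to_csv(p, sep="\t"), exp_df)
        report["stages"]["rna"] = {
            "n_candidates": len(filtered), "n_passing": len(passed),
            "n_regions_fit": len(exposures)}

    (outdir / "manifest.json").write_text(json.dumps(report, indent=2,
                                                     sort_keys=True))
    return report
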