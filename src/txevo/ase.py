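"""Allele-specific expression (ASE) testing under allele-specific copy number.

Per heterozygous SNP, three beta-binomial tests are computed on the RNA
major-allele count ``m`` out of total coverage ``t`` (the *major* allele is
the one with more reads in matched DNA):

* test 1:  P(X >= m | t, 0.5)          -- imbalance versus equal expression
* test 3:  P(X <  m | t, 0.5)          -- major allele *under*-expressed
* test 4:  P(X >= m | t, CPNratio)     -- imbalance beyond the DNA copy-number
                                          ratio (major CN / total CN)

An independent filter ``CPNratio ** t < 0.001`` removes SNPs whose coverage
or copy-number ratio leaves no power (e.g. LOH, extreme amplification).
Per gene and sample, p-values are Fisher-combined into two statistics:
A (test 1) and B (per-SNP min of tests 3 and 4).  After Benjamini-Hochberg
correction across the genes of a sample, FDR_B < 0.05 calls
copy-number-independent ASE; FDR_A < 0.05 without FDR_B < 0.05 calls
copy-number-dependent ASE.

The module also provides downstream summaries: annotation enrichment odds
ratios, intratumour heterogeneity of CN-independent ASE, reference-bias
quantification, a promoter allele-specific-methylation (ASM) rule and
mirrored subclonal allelic imbalance (MSAI) detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .betabin import betabin_lower, betabin_tail

logger = logging.getLogger(__name__)

DEFAULT_RHO = 0.05
INDEPENDENT_FILTER_P = 1e-3
ASE_FDR = 0.05
MIN_RNA_COVERAGE = 8  # strict: t must exceed this
_P_FLOOR = 1e-300

#: required columns of a SNP allele-count table
SNP_COLUMNS = [
    "snp_id", "gene_id", "tumour_id", "region_id", "chrom", "pos",
    "dna_major_count", "dna_minor_count", "rna_major_count",
    "rna_minor_count", "major_cn", "minor_cn", "major_is_reference",
]


# ---------------------------------------------------------------------------
# per-SNP tests
# ---------------------------------------------------------------------------

def independent_filter(t, cpn_ratio):
    """Keep a SNP iff the binomial criterion P(X >= t | t, CPNratio)
    = CPNratio**t falls below 0.001.

    Removes sites with low read counts and/or extreme copy-number ratios.
    Vectorised; returns bool (array)."""
    t = np.asarray(t, dtype=float)
    cpn = np.asarray(cpn_ratio, dtype=float)
    if np.any((cpn < 0) | (cpn > 1)):
        raise ValueError("cpn_ratio must lie in [0, 1]")
    keep = np.power(cpn, t) < INDEPENDENT_FILTER_P
    return keep if keep.ndim else bool(keep)


def test_snps(snps: pd.DataFrame, rho: float = DEFAULT_RHO) -> pd.DataFrame:
    """Apply the three per-SNP beta-binomial tests to an allele-count table.

    ``snps`` needs columns ``rna_major_count``, ``rna_minor_count``,
    ``major_cn``, ``minor_cn``.  Returns a copy with added columns
    ``total_rna``, ``cpn_ratio``, ``evaluable`` (coverage > 8),
    ``passes_independent_filter``, ``p_eq1``, ``p_eq3``, ``p_eq4``.

    SNPs with a copy-number ratio of exactly 0 or 1 (LOH) cannot be tested
    against the CN expectation: cpn_ratio == 1 fails the independent filter
    by construction and cpn_ratio == 0 is inconsistent with expressed
    heterozygosity, so both are marked as not passing.
    """
    out = snps.copy()
    m = out["rna_major_count"].to_numpy(dtype=np.int64)
    t = m + out["rna_minor_count"].to_numpy(dtype=np.int64)
    total_cn = out["major_cn"].to_numpy(float) + out["minor_cn"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cpn = np.where(total_cn > 0, out["major_cn"].to_numpy(float) / total_cn, np.nan)
    out["total_rna"] = t
    out["cpn_ratio"] = cpn

    evaluable = t > MIN_RNA_COVERAGE
    interior = (cpn > 0.0) & (cpn < 1.0)
    keep = np.zeros(len(out), dtype=bool)
    ok = evaluable & ~np.isnan(cpn)
    keep[ok] = independent_filter(t[ok], cpn[ok]) & interior[ok]

    p1 = np.full(len(out), np.nan)
    p3 = np.full(len(out), np.nan)
    p4 = np.full(len(out), np.nan)
    if evaluable.any():
        idx = np.flatnonzero(evaluable)
        p1[idx] = betabin_tail(m[idx], t[idx], 0.5, rho)
        p3[idx] = betabin_lower(m[idx], t[idx], 0.5, rho)
    usable = evaluable & interior
    if usable.any():
        idx = np.flatnonzero(usable)
        p4[idx] = betabin_tail(m[idx], t[idx], cpn[idx], rho)

    out["evaluable"] = evaluable
    out["passes_independent_filter"] = keep
    out["p_eq1"] = p1
    out["p_eq3"] = p3
    out["p_eq4"] = p4
    return out


# ---------------------------------------------------------------------------
# gene-level combination and classification
# ---------------------------------------------------------------------------

def fisher_combine(pvalues) -> float:
    """Fisher's method: -2 sum(log p) ~ chi2 on 2k df.  P-values are clipped
    at 1e-300 before the log; k = 1 returns the p-value unchanged."""
    p = np.clip(np.asarray(pvalues, dtype=float), _P_FLOOR, 1.0)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    stat = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(stat, 2 * p.size))


def combine_genes(snp_results: pd.DataFrame) -> pd.DataFrame:
    """Fisher-combine per-SNP p-values into gene x region statistics.

    Only evaluable, filter-passing SNPs contribute.  Returns one row per
    (tumour_id, region_id, gene_id) present in the input, with
    ``p_combined_A`` (test 1), ``p_combined_B`` (per-SNP min of tests 3/4)
    and ``n_snps_used``; genes without a usable SNP get NaN p-values and
    ``n_snps_used = 0``.
    """
    keys = ["tumour_id", "region_id", "gene_id"]
    rows = []
    for key, grp in snp_results.groupby(keys, sort=False):
        use = grp[grp["evaluable"] & grp["passes_independent_filter"]]
        if len(use) == 0:
            rows.append((*key, 0, np.nan, np.nan))
            continue
        p_a = fisher_combine(use["p_eq1"])
        p_b = fisher_combine(np.minimum(use["p_eq3"], use["p_eq4"]))
        rows.append((*key, len(use), p_a, p_b))
    return pd.DataFrame(rows, columns=keys + ["n_snps_used", "p_combined_A", "p_combined_B"])


def classify_cohort(gene_results: pd.DataFrame, alpha: float = ASE_FDR) -> pd.DataFrame:
    """Benjamini-Hochberg correct combined p-values within each sample
    (tumour region) across genes and attach ASE labels.

    Labels partition the evaluable genes: ``cn_independent_ase`` iff
    FDR_B < alpha; ``cn_dependent_ase`` iff FDR_A < alpha and FDR_B >= alpha;
    otherwise ``biallelic``.  Genes without usable SNPs are ``not_evaluable``.
    """
    out = gene_results.copy()
    if len(out) == 0:
        out["fdr_A"] = out["fdr_B"] = pd.Series(dtype=float)
        out["label"] = pd.Series(dtype=object)
        return out
    out["fdr_A"] = np.nan
    out["fdr_B"] = np.nan
    for _, idx in out.groupby(["tumour_id", "region_id"], sort=False).groups.items():
        sub = out.loc[idx]
        ok = sub["n_snps_used"] > 0
        if ok.any():
            for col, fdr_col in (("p_combined_A", "fdr_A"), ("p_combined_B", "fdr_B")):
                adj = multipletests(sub.loc[ok, col].to_numpy(), method="fdr_bh")[1]
                out.loc[sub.index[ok], fdr_col] = adj
    label = np.where(
        out["n_snps_used"] == 0, "not_evaluable",
        np.where(out["fdr_B"] < alpha, "cn_independent_ase",
                 np.where(out["fdr_A"] < alpha, "cn_dependent_ase", "biallelic")))
    out["label"] = label
    return out


def run_ase(snps: pd.DataFrame, rho: float = DEFAULT_RHO,
            alpha: float = ASE_FDR) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: per-SNP tests, combination and classification.

    Returns ``(snp_results, gene_results)``."""
    snp_res = test_snps(snps, rho=rho)
    gene_res = classify_cohort(combine_genes(snp_res), alpha=alpha)
    return snp_res, gene_res


# ---------------------------------------------------------------------------
# downstream summaries
# ---------------------------------------------------------------------------

@dataclass
class OddsRatioResult:
    odds_ratio: float
    pvalue: float
    table: np.ndarray
    defined: bool = True


def odds_ratio_from_table(table, alternative: str = "two-sided") -> OddsRatioResult:
    """Sample (cross-product) odds ratio with Haldane 0.5 correction applied
    to all cells when any cell is zero, plus a Fisher exact p-value on the
    raw table.  Degenerate margins return a flagged, undefined result."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise ValueError("need a nonnegative 2x2 table")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        return OddsRatioResult(np.nan, np.nan, tab, defined=False)
    work = tab + 0.5 if np.any(tab == 0) else tab
    or_ = (work[0, 0] * work[1, 1]) / (work[0, 1] * work[1, 0])
    p = stats.fisher_exact(tab.astype(np.int64), alternative=alternative).pvalue
    return OddsRatioResult(float(or_), float(p), tab)


def enrichment_odds_ratio(ase: pd.Series, annotation: pd.Series,
                          alternative: str = "two-sided") -> OddsRatioResult:
    """Odds of carrying an annotation (e.g. imprinted, stop-gain) at ASE
    versus non-ASE genes, over genes powered to detect ASE.  Both inputs are
    boolean Series aligned on gene identifier."""
    ase, annotation = ase.align(annotation, join="inner")
    a = ase.astype(bool)
    b = annotation.astype(bool)
    table = [[int((a & b).sum()), int((a & ~b).sum())],
             [int((~a & b).sum()), int((~a & ~b).sum())]]
    return odds_ratio_from_table(table, alternative=alternative)


def cn_indep_ase_ith(labels: pd.DataFrame) -> float:
    """Intratumour heterogeneity of CN-independent ASE for one tumour.

    ``labels`` has one row per (gene_id, region_id) with a ``label`` column.
    A gene qualifies if it shows CN-independent ASE in at least two regions;
    it is *homogeneous* if additionally it shows it in every region where it
    was evaluable (requiring >= 2 evaluable regions).  Returns
    ``1 - homogeneous fraction``; NaN when no gene qualifies.
    """
    if labels["region_id"].nunique() < 2:
        raise ValueError("tumour must have >= 2 regions")
    n_qual = 0
    n_homog = 0
    for _, g in labels.groupby("gene_id", sort=False):
        ev = g[g["label"] != "not_evaluable"]
        hits = (ev["label"] == "cn_independent_ase").sum()
        if hits >= 2:
            n_qual += 1
            if len(ev) >= 2 and hits == len(ev):
                n_homog += 1
    if n_qual == 0:
        return float("nan")
    return 1.0 - n_homog / n_qual


def reference_bias(n_ref_over: int, n_alt_over: int) -> float:
    """Per-sample reference bias: CN-independent events where the reference
    allele is over-expressed divided by events where the alternative allele
    is; infinite (flagged as ``inf``) when the denominator is zero."""
    if n_ref_over < 0 or n_alt_over < 0:
        raise ValueError("counts must be nonnegative")
    if n_alt_over == 0:
        return float("inf")
    return n_ref_over / n_alt_over


def reference_bias_from_results(snp_results: pd.DataFrame,
                                gene_results: pd.DataFrame) -> float:
    """Derive the reference-bias ratio of a sample from classified results.

    For each CN-independent gene the over-expressed allele is the major
    allele if the evidence came from test 4 (min p on eq4 side) and the
    minor allele if it came from test 3; per-SNP votes are aggregated by
    majority, combined with ``major_is_reference``.
    """
    hits = gene_results[gene_results["label"] == "cn_independent_ase"]
    n_ref = n_alt = 0
    keyed = snp_results.set_index(["tumour_id", "region_id", "gene_id"])
    for _, row in hits.iterrows():
        snps = keyed.loc[[(row["tumour_id"], row["region_id"], row["gene_id"])]]
        snps = snps[snps["evaluable"] & snps["passes_independent_filter"]]
        if len(snps) == 0:
            continue
        major_over = (snps["p_eq4"] <= snps["p_eq3"]).to_numpy()
        ref_is_major = snps["major_is_reference"].to_numpy(bool)
        ref_over = np.where(major_over, ref_is_major, ~ref_is_major)
        if ref_over.mean() > 0.5:
            n_ref += 1
        else:
            n_alt += 1
    return reference_bias(n_ref, n_alt)


# ---------------------------------------------------------------------------
# promoter allele-specific methylation
# ---------------------------------------------------------------------------

ASM_HDI_BOUNDS = (0.15, 0.75)
ASM_POINT_BOUNDS = (0.2, 0.7)
ASM_MIN_RUN = 3


def is_asm_locus(point, hdi_low, hdi_high):
    """A CpG is an ASM locus iff its 99% highest-density interval lies inside
    [0.15, 0.75] and its point methylation rate inside [0.2, 0.7]
    (intermediate tumour methylation as a proxy for allelic methylation)."""
    point = np.asarray(point, dtype=float)
    lo = np.asarray(hdi_low, dtype=float)
    hi = np.asarray(hdi_high, dtype=float)
    ok = ((lo >= ASM_HDI_BOUNDS[0]) & (hi <= ASM_HDI_BOUNDS[1])
          & (point >= ASM_POINT_BOUNDS[0]) & (point <= ASM_POINT_BOUNDS[1]))
    return ok if ok.ndim else bool(ok)


def classify_promoter_asm(cpgs: pd.DataFrame) -> bool:
    """Promoter-level ASM call: at least three *consecutive* ASM loci among
    the promoter CpGs ordered by position."""
    if len(cpgs) < ASM_MIN_RUN:
        return False
    ordered = cpgs.sort_values("position")
    flags = is_asm_locus(ordered["m_t_point"], ordered["hdi99_low"],
                         ordered["hdi99_high"])
    run = best = 0
    for f in np.atleast_1d(flags):
        run = run + 1 if f else 0
        best = max(best, run)
    return best >= ASM_MIN_RUN


# ---------------------------------------------------------------------------
# mirrored subclonal allelic imbalance
# ---------------------------------------------------------------------------

MSAI_ALPHA = 0.05


def detect_msai(snp_results: pd.DataFrame, gene_results: pd.DataFrame,
                alpha: float = MSAI_ALPHA) -> pd.DataFrame:
    """Detect mirrored subclonal allelic imbalance across the regions of one
    tumour.

    Requires phased input: columns ``phase_block_id`` (NaN = unphased,
    skipped with a log notice) and ``major_is_hap1`` linking each SNP's
    DNA-major allele to a haplotype of its block.  Two event types:

    * ``genomic`` -- two regions each show significant DNA allelic imbalance
      (two-sided binomial test on pooled haplotype read counts, p < alpha)
      but with *different* major haplotypes.
    * ``genomic_transcriptomic`` -- a region without DNA imbalance is called
      CN-independent ASE favouring the haplotype that is reduced in another,
      DNA-imbalanced region.

    Returns a DataFrame of events (gene, type, regions, haplotypes).
    """
    labels = gene_results.set_index(["region_id", "gene_id"])["label"]
    events = []
    for gene, grp in snp_results.groupby("gene_id", sort=False):
        if grp["phase_block_id"].isna().any():
            logger.info("gene %s skipped for MSAI: unphased SNPs", gene)
            continue
        per_region = {}
        for region, sub in grp.groupby("region_id", sort=False):
            maj1 = sub["major_is_hap1"].to_numpy(bool)
            d_h1 = int(np.where(maj1, sub["dna_major_count"], sub["dna_minor_count"]).sum())
            d_tot = int(sub["dna_major_count"].sum() + sub["dna_minor_count"].sum())
            r_h1 = int(np.where(maj1, sub["rna_major_count"], sub["rna_minor_count"]).sum())
            r_tot = int(sub["rna_major_count"].sum() + sub["rna_minor_count"].sum())
            p_dna = stats.binomtest(d_h1, d_tot, 0.5).pvalue if d_tot else 1.0
            per_region[region] = {
                "dna_imbalanced": p_dna < alpha,
                "dna_major_hap": 1 if d_h1 * 2 >= d_tot else 2,
                "rna_favoured_hap": 1 if r_tot and r_h1 * 2 >= r_tot else 2,
            }
        regions = list(per_region)
        if len(regions) < 2:
            continue
        imb = [r for r in regions if per_region[r]["dna_imbalanced"]]
        # genomic MSAI: opposite haplotypes amplified/retained in two regions
        for i, r1 in enumerate(imb):
            for r2 in imb[i + 1:]:
                if per_region[r1]["dna_major_hap"] != per_region[r2]["dna_major_hap"]:
                    events.append((gene, "genomic", r1, r2,
                                   per_region[r1]["dna_major_hap"],
                                   per_region[r2]["dna_major_hap"]))
        # genomic-transcriptomic MSAI
        for r in regions:
            if per_region[r]["dna_imbalanced"]:
                continue
            if labels.get((r, gene), None) != "cn_independent_ase":
                continue
            fav = per_region[r]["rna_favoured_hap"]
            for r2 in imb:
                lost_hap = 3 - per_region[r2]["dna_major_hap"]
                if fav == lost_hap:
                    events.append((gene, "genomic_transcriptomic", r, r2,
                                   fav, per_region[r2]["dna_major_hap"]))
    return pd.DataFrame(
        events, columns=["gene_id", "event_type", "region_1", "region_2",
                         "hap_region_1", "hap_region_2"])
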