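"""Expression normalisation, intratumour expression distance (I-TED) and
tumour-transcript-fraction estimation.

I-TED quantifies transcriptomic intratumour heterogeneity without depending
on the number of regions sampled: for each region of a multiregion tumour,
1 minus the distance correlation (energy-statistics V-statistic) against
every other region of the same tumour is averaged, over the top 500 most
variable genes of the normalised, log-transformed cohort matrix; the
tumour-level value is the median over its regions.

The tumour transcript fraction is the RNA analogue of DNA purity: the
ploidy-adjusted proportion of transcripts derived from tumour cells.  It is
estimated from RNA B-allele frequencies at heterozygous SNPs in segments of
known allele-specific copy number, by a least-squares grid search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "median_of_ratios_normalize", "filter_expressed_genes",
    "distance_correlation", "ited", "estimate_transcript_fraction",
    "TranscriptFractionFit",
]


def median_of_ratios_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalisation (genes x regions).

    The reference set is the genes with nonzero counts in every region.  Each
    region's size factor is the median, over reference genes, of the ratio of
    its count to the gene's geometric mean; normalised counts are the raw
    counts divided by the size factor.  Returns (normalised, size_factors).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two regions")
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be nonnegative")
    ref = (mat > 0).all(axis=1)
    if not ref.any():
        raise ValueError("no gene has nonzero counts in all regions")
    logs = np.log(mat[ref])
    log_gm = logs.mean(axis=1, keepdims=True)
    size_factors = np.exp(np.median(logs - log_gm, axis=0))
    sf = pd.Series(size_factors, index=counts.columns, name="size_factor")
    return counts / sf, sf


def filter_expressed_genes(counts: pd.DataFrame, min_count: int = 5,
                           min_frac: float = 0.2) -> pd.Index:
    """Genes with counts strictly above ``min_count`` in at least
    ``min_frac`` of regions (default: > 5 reads in >= 20% of the cohort)."""
    frac = (counts > min_count).mean(axis=1)
    return counts.index[frac >= min_frac]


def distance_correlation(x, y) -> float:
    """Empirical distance correlation (biased V-statistic).

    Pairwise absolute-difference matrices are double-centred and the
    correlation of the centred matrices taken; the result lies in [0, 1]
    and equals 1 under exact linear dependence.  A constant input vector is
    degenerate and returns NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-d vectors of length >= 2")
    a = np.abs(x[:, None] - x[None, :])
    b = np.abs(y[:, None] - y[None, :])
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return float("nan")
    dcov2 = (A * B).mean()
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def _log_transform(normalized: pd.DataFrame) -> pd.DataFrame:
    return np.log2(normalized + 1.0)


def top_variable_genes(transformed: pd.DataFrame, n_top: int = 500) -> pd.Index:
    """Rank genes by variance of the transformed values across all cohort
    regions; ties are broken by gene identifier for determinism."""
    var = transformed.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], str(g)))
    return pd.Index(order[:n_top])


def ited(counts: pd.DataFrame, region_to_tumour: pd.Series,
         transform=_log_transform, n_top: int = 500,
         min_count: int = 5, min_frac: float = 0.2) -> pd.DataFrame:
    """Region- and tumour-level I-TED for a cohort counts matrix.

    Counts are median-of-ratios normalised, gene-filtered, transformed
    (default log2(x+1) as a variance-stabilising stand-in, pluggable) and the
    top ``n_top`` most variable genes retained.  Region I-TED is the mean of
    (1 - distance correlation) against the other regions of the same tumour;
    tumour I-TED is the median of its region values.  Single-region tumours
    are flagged NaN (not computable).
    """
    normalized, _ = median_of_ratios_normalize(counts)
    keep = filter_expressed_genes(counts, min_count=min_count, min_frac=min_frac)
    transformed = transform(normalized.loc[keep])
    genes = top_variable_genes(transformed, n_top=n_top)
    sub = transformed.loc[genes]

    rows = []
    for tumour, regions in region_to_tumour.groupby(region_to_tumour):
        region_ids = list(regions.index)
        if len(region_ids) < 2:
            for r in region_ids:
                rows.append((r, tumour, np.nan, np.nan))
            continue
        vals = {}
        for r in region_ids:
            others = [o for o in region_ids if o != r]
            d = [1.0 - distance_correlation(sub[r].to_numpy(), sub[o].to_numpy())
                 for o in others]
            vals[r] = float(np.mean(d))
        med = float(np.median(list(vals.values())))
        for r in region_ids:
            rows.append((r, tumour, vals[r], med))
    return pd.DataFrame(rows, columns=["region_id", "tumour_id",
                                       "ited_region", "ited_tumour"])


# ---------------------------------------------------------------------------
# tumour transcript fraction
# ---------------------------------------------------------------------------

@dataclass
class TranscriptFractionFit:
    rho_rna: float
    fit_loss: float
    identifiable: bool
    n_snps: int


def model_major_baf(rho, major_cn, minor_cn):
    """Expected major-allele RNA fraction in an admixed sample with tumour
    transcript fraction ``rho``: non-tumour cells contribute one copy of each
    allele (diploid), tumour cells contribute the allele-specific copy
    numbers, with equal expression per copy."""
    rho = np.asarray(rho, dtype=float)
    nA = np.asarray(major_cn, dtype=float)
    nB = np.asarray(minor_cn, dtype=float)
    num = rho * nA + (1.0 - rho)
    den = rho * (nA + nB) + 2.0 * (1.0 - rho)
    return num / den


def estimate_transcript_fraction(snps: pd.DataFrame,
                                 grid_step: float = 0.001) -> TranscriptFractionFit:
    """Least-squares grid search for the tumour transcript fraction.

    ``snps`` has one row per heterozygous SNP with columns ``baf`` (RNA
    major-allele fraction, oriented to the DNA-major allele), ``major_cn``
    and ``minor_cn`` of the containing segment.  The grid covers [0, 1] in
    ``grid_step`` increments; ties resolve to the smallest rho.  With no
    allelically imbalanced segment the model is constant in rho and the fit
    is flagged unidentifiable.
    """
    if len(snps) == 0:
        raise ValueError("no SNPs supplied")
    baf = snps["baf"].to_numpy(dtype=float)
    nA = snps["major_cn"].to_numpy(dtype=float)
    nB = snps["minor_cn"].to_numpy(dtype=float)
    identifiable = bool(np.any(nA != nB))
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    pred = model_major_baf(grid[:, None], nA[None, :], nB[None, :])
    loss = ((pred - baf[None, :]) ** 2).sum(axis=1)
    if not identifiable:
        return TranscriptFractionFit(float("nan"), float(loss[0]), False, len(snps))
    i = int(np.argmin(loss))
    return TranscriptFractionFit(float(grid[i]), float(loss[i]), True, len(snps))
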