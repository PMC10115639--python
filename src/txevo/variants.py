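"""Post-caller filtering of candidate RNA-only substitutions.

Candidate RNA variants (single-base changes seen in RNA-seq but absent from
DNA) pass a battery of depth, support and context filters before signature
analysis:

* >= 30 reads in germline DNA and >= 30 total reads across tumour DNA
  regions (enough DNA evidence that the site is *not* a DNA mutation);
* RNA coverage >= 10, alternative allele supported by >= 3 RNA reads and a
  variant allele frequency of at least 1% (1% exactly passes);
* any DNA reads supporting the variant must be indistinguishable from
  sequencing noise (one-tailed Fisher test, lenient p < 0.1 excludes);
* sites flanked by a 4-base homopolymer of the reference or alternative
  base are excluded, as are sites in blacklisted genomic intervals.

Each failed rule is recorded as a named flag; a variant passes iff it
carries no flag, so the filter is order-independent by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MIN_GERMLINE_DNA = 30
MIN_TUMOUR_DNA = 30
MIN_RNA_DEPTH = 10
MIN_ALT_SUPPORT = 3
MIN_VAF = 0.01
NOISE_P = 0.1

FILTER_FLAGS = [
    "low_germline_dna", "low_tumour_dna", "low_rna_coverage",
    "low_alt_support", "low_vaf", "dna_support", "homopolymer_flank",
    "blacklist",
]


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def dna_noise_test(dna_alt_support: int, dna_error_support: int,
                   dna_depth: int) -> tuple[float, bool]:
    """Is DNA support for the RNA variant distinguishable from sequencing
    noise?

    One-tailed Fisher test on [[alt_support, depth - alt_support],
    [error_support, depth - error_support]]; the variant is excluded iff
    p < 0.1.  Zero depth or zero alt support keeps the variant (p = 1).
    Returns (p, exclude).
    """
    if dna_depth < max(dna_alt_support, dna_error_support):
        raise ValueError("depth must be >= supports")
    if dna_depth == 0 or dna_alt_support == 0:
        return 1.0, False
    table = [[dna_alt_support, dna_depth - dna_alt_support],
             [dna_error_support, dna_depth - dna_error_support]]
    p = float(stats.fisher_exact(table, alternative="greater").pvalue)
    return p, p < NOISE_P


def flank_filter(ref: str, alt: str, context5: str, context3: str) -> bool:
    """Keep (True) unless either 4-base flank is a homopolymer of the
    reference or alternative base."""
    homos = {ref * 4, alt * 4}
    return context5 not in homos and context3 not in homos


def _blacklist_lookup(blacklist: pd.DataFrame | None):
    """Build a vectorisable (chrom, 1-based pos) -> bool membership test from
    a BED-style frame (chrom, start, end; 0-based half-open)."""
    if blacklist is None or len(blacklist) == 0:
        return lambda chrom, pos: np.zeros(len(pos), dtype=bool)
    by_chrom = {}
    for chrom, grp in blacklist.groupby(blacklist.columns[0]):
        iv = grp.iloc[:, 1:3].to_numpy(dtype=np.int64)
        iv = iv[np.argsort(iv[:, 0])]
        by_chrom[chrom] = (iv[:, 0], iv[:, 1])

    def contains(chroms, pos):
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # to 0-based
        out = np.zeros(len(pos0), dtype=bool)
        chroms = np.asarray(chroms)
        for chrom, (starts, ends) in by_chrom.items():
            sel = chroms == chrom
            if not sel.any():
                continue
            idx = np.searchsorted(starts, pos0[sel], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(sel.sum(), dtype=bool)
            hit[ok] = pos0[sel][ok] < ends[idx[ok]]
            out[sel] = hit
        return out

    return contains


def filter_variants(candidates: pd.DataFrame,
                    blacklist: pd.DataFrame | None = None) -> pd.DataFrame:
    """Apply all post-caller filters, returning a copy of ``candidates``
    with one boolean column per flag in :data:`FILTER_FLAGS`, a ``flags``
    string column (comma-joined) and a ``passes`` column.

    Required columns: rna_depth, rna_alt, dna_germline_depth,
    dna_tumour_depth_total, dna_alt_support, dna_error_support, ref, alt,
    context5, context3, chrom, pos (1-based).
    """
    out = candidates.copy()
    rna_depth = out["rna_depth"].to_numpy(np.int64)
    rna_alt = out["rna_alt"].to_numpy(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(rna_depth > 0, rna_alt / rna_depth, 0.0)
    out["vaf"] = vaf

    out["low_germline_dna"] = out["dna_germline_depth"].to_numpy(np.int64) < MIN_GERMLINE_DNA
    out["low_tumour_dna"] = out["dna_tumour_depth_total"].to_numpy(np.int64) < MIN_TUMOUR_DNA
    out["low_rna_coverage"] = rna_depth < MIN_RNA_DEPTH
    out["low_alt_support"] = rna_alt < MIN_ALT_SUPPORT
    out["low_vaf"] = vaf < MIN_VAF

    noise = [dna_noise_test(int(a), int(e), int(d))[1]
             for a, e, d in zip(out["dna_alt_support"], out["dna_error_support"],
                                out["dna_tumour_depth_total"])]
    out["dna_support"] = noise

    out["homopolymer_flank"] = [
        not flank_filter(r, a, c5, c3)
        for r, a, c5, c3 in zip(out["ref"], out["alt"],
                                out["context5"], out["context3"])]

    contains = _blacklist_lookup(blacklist)
    out["blacklist"] = contains(out["chrom"].to_numpy(), out["pos"].to_numpy())

    flag_mat = out[FILTER_FLAGS].to_numpy(bool)
    out["passes"] = ~flag_mat.any(axis=1)
    out["flags"] = [",".join(f for f, on in zip(FILTER_FLAGS, row) if on)
                    for row in flag_mat]
    return out


def dedupe_per_patient(variants: pd.DataFrame) -> pd.DataFrame:
    """Unique RNA variants across all regions of one patient, keyed by
    (chrom, pos, ref, alt); the first occurrence is retained."""
    return variants.drop_duplicates(subset=["chrom", "pos", "ref", "alt"])


# ---------------------------------------------------------------------------
# hairpin (RNA loop) detection
# ---------------------------------------------------------------------------

def detect_hairpin(seq: str, variant_offset: int, loop_range=(3, 5),
                   min_stem: int = 3) -> bool:
    """Does the variant sit inside the loop of a potential RNA hairpin?

    A hairpin is called when some window of 3-5 bases containing the variant
    has flanking 5' and 3' stems of at least ``min_stem`` bases that are
    reverse complements of each other (the 5' stem pairs with the 3' stem).
    Windows that would run past the supplied sequence are not considered.
    """
    n = len(seq)
    if not 0 <= variant_offset < n:
        raise ValueError("variant offset outside sequence")
    seq = seq.upper()
    for loop_len in range(loop_range[0], loop_range[1] + 1):
        for start in range(variant_offset - loop_len + 1, variant_offset + 1):
            end = start + loop_len
            if start - min_stem < 0 or end + min_stem > n:
                continue
            left = seq[start - min_stem:start]
            right = seq[end:end + min_stem]
            if left == revcomp(right):
                return True
    return False
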