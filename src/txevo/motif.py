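"""Local enrichment of C>T RNA edits at APOBEC3A-favoured motifs.

APOBEC3A deaminates cytidine in single-stranded RNA with a strong preference
for the CAT[C>T] motif (the edited C at the fourth position of a hairpin
loop).  For each C>T variant site, a one-tailed Fisher test asks whether
C>T changes within the surrounding +/-20 nucleotides occur at motif
cytosines more often than the local motif opportunity would predict, on
either strand (a minus-strand CATC reads [G]ATG on the plus strand).

The opportunity denominator is every C (plus strand) or G (minus strand)
position in the window; the variant numerator is every *other* C>T / G>A
variant in the window (sites with no neighbouring C>T are skipped with
p = 1).  A pooled cohort-level table is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FLANK = 20
DEFAULT_MOTIF = "CAT"


def _is_ct(ref: str, alt: str) -> bool:
    """C>T on either strand: plus-strand C>T or its complement G>A."""
    return (ref, alt) in {("C", "T"), ("G", "A")}


def _motif_positions(seq: str, motif: str = DEFAULT_MOTIF):
    """0-based offsets of motif-context C positions (plus strand: C preceded
    by the motif; minus strand: G followed by the reverse complement)."""
    from .variants import revcomp
    k = len(motif)
    rc = revcomp(motif)
    plus, minus = set(), set()
    for i, base in enumerate(seq):
        if base == "C" and i >= k and seq[i - k:i] == motif:
            plus.add(i)
        if base == "G" and seq[i + 1:i + 1 + k] == rc:
            minus.add(i)
    return plus, minus


@dataclass
class MotifEnrichmentResult:
    per_site: pd.DataFrame
    pooled_table: np.ndarray
    pooled_odds_ratio: float
    pooled_pvalue: float


def apobec_motif_enrichment(variants: pd.DataFrame, reference,
                            flank: int = DEFAULT_FLANK,
                            motif: str = DEFAULT_MOTIF) -> MotifEnrichmentResult:
    """Per-site and pooled motif enrichment of C>T variants.

    ``variants`` holds columns chrom, pos (1-based), ref, alt; only C>T /
    G>A records are used.  ``reference`` maps chrom -> sequence string (a
    dict or pyfaidx-like object convertible with str()).  Per site, the
    2x2 table is [[motif variants, non-motif variants], [motif C/G
    positions, non-motif C/G positions]] within the window; windows with no
    C>T variants record p = 1 and are flagged skipped.
    """
    ct = variants[[_is_ct(r, a) for r, a in zip(variants["ref"], variants["alt"])]]
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy(np.int64))
                    for c, g in ct.groupby("chrom")}
    rows = []
    pooled = np.zeros((2, 2), dtype=np.int64)
    for _, site in ct.iterrows():
        chrom, pos = site["chrom"], int(site["pos"])
        seq = str(reference[chrom]).upper()
        lo = max(0, pos - 1 - flank)
        hi = min(len(seq), pos + flank)
        window = seq[lo:hi]
        plus, minus = _motif_positions(seq, motif)
        # opportunity positions: every C (plus-strand) and G (minus-strand)
        opp = [i for i in range(lo, hi) if seq[i] in "CG"]
        motif_opp = sum(1 for i in opp if i in plus or i in minus)
        nonmotif_opp = len(opp) - motif_opp

        in_window = pos_by_chrom[chrom]
        in_window = in_window[(in_window >= lo + 1) & (in_window <= hi)
                              & (in_window != pos)]
        motif_var = 0
        for p1 in in_window:
            i = p1 - 1
            if i in plus or i in minus:
                motif_var += 1
        nonmotif_var = len(in_window) - motif_var

        if len(in_window) == 0:
            rows.append((chrom, pos, 0, 0, motif_opp, nonmotif_opp,
                         np.nan, 1.0, True))
            continue
        table = np.array([[motif_var, nonmotif_var],
                          [motif_opp, nonmotif_opp]], dtype=np.int64)
        res = stats.fisher_exact(table, alternative="greater")
        odds = (motif_var * nonmotif_opp) / (nonmotif_var * motif_opp) \
            if nonmotif_var and motif_opp else np.nan
        rows.append((chrom, pos, motif_var, nonmotif_var, motif_opp,
                     nonmotif_opp, odds, float(res.pvalue), False))
        pooled += table
    per_site = pd.DataFrame(rows, columns=[
        "chrom", "pos", "motif_variants", "nonmotif_variants",
        "motif_positions", "nonmotif_positions", "odds_ratio", "pvalue",
        "skipped"])
    if pooled.sum() > 0 and pooled[0].sum() > 0:
        pres = stats.fisher_exact(pooled, alternative="greater")
        work = pooled + 0.5 if np.any(pooled == 0) else pooled
        pooled_or = float(work[0, 0] * work[1, 1] / (work[0, 1] * work[1, 0]))
        pooled_p = float(pres.pvalue)
    else:
        pooled_or, pooled_p = float("nan"), 1.0
    return MotifEnrichmentResult(per_site, pooled, pooled_or, pooled_p)
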