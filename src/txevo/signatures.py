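"""Strand-aware 192-channel RNA substitution spectra and signatures.

Because RNA-seq libraries are stranded, an RNA substitution is assigned to
the strand of its annotated transcript, giving 12 substitution classes
(every ordered ref>alt pair) rather than the 6 pyrimidine-collapsed classes
of DNA mutational signatures.  With the 5' and 3' neighbouring bases this
yields 12 x 4 x 4 = 192 channels representing the substitution on the
transcribed (mRNA-sense) strand; variants in '-' transcripts are reverse
complemented (base and context) before channel assignment.

Channel order is lexicographic in (ref, alt, 5' base, 3' base) and emitted
with every spectrum; no community standard exists for 192-channel RNA
spectra, so the ordering here is the package's documented convention.

Exposure fitting is plain non-negative least squares of the normalised
spectrum on the signature matrix; de novo extraction is a seeded NMF
(a deterministic stand-in for hierarchical Dirichlet process methods).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import NMF

from .variants import revcomp

BASES = "ACGT"
SUBSTITUTIONS = [(r, a) for r in BASES for a in BASES if r != a]
CHANNELS = [f"{f}[{r}>{a}]{t}"
            for (r, a) in SUBSTITUTIONS for f in BASES for t in BASES]
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}
N_CHANNELS = len(CHANNELS)  # 192
MIN_VARIANTS_FOR_EXPOSURE = 20  # region needs *more than* this many variants


def channel_name(up: str, ref: str, alt: str, down: str) -> str:
    return f"{up}[{ref}>{alt}]{down}"


def parse_channel(name: str) -> tuple[str, str, str, str]:
    """Inverse of :func:`channel_name`: returns (up, ref, alt, down)."""
    return name[0], name[2], name[4], name[6]


def revcomp_channel(name: str) -> str:
    """Map a channel to its opposite-strand equivalent; an involution over
    all 192 channels."""
    up, ref, alt, down = parse_channel(name)
    return channel_name(revcomp(down), revcomp(ref), revcomp(alt), revcomp(up))


def build_spectrum(variants: pd.DataFrame) -> pd.Series:
    """Count variants into the 192 strand-aware channels.

    Needs columns ``ref``, ``alt``, ``up``, ``down`` (genomic single-base
    context) and ``transcript_strand`` ('+'/'-').  Minus-strand variants are
    reverse complemented so channels are mRNA-sense.  Variants with
    ambiguous bases are skipped; the count of skips is stored in
    ``spectrum.attrs['n_skipped']`` and the total otherwise equals the
    number of variants.
    """
    counts = np.zeros(N_CHANNELS, dtype=np.int64)
    skipped = 0
    for ref, alt, up, down, strand in zip(
            variants["ref"], variants["alt"], variants["up"],
            variants["down"], variants["transcript_strand"]):
        if strand == "-":
            ref, alt = revcomp(ref), revcomp(alt)
            up, down = revcomp(down), revcomp(up)
        name = channel_name(up, ref, alt, down)
        idx = CHANNEL_INDEX.get(name)
        if idx is None:
            skipped += 1
            continue
        counts[idx] += 1
    spectrum = pd.Series(counts, index=CHANNELS, name="count")
    spectrum.attrs["n_skipped"] = skipped
    return spectrum


def cosine_similarity(a, b) -> float:
    """Cosine of two spectra (scale-invariant, in [0, 1] for counts)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for an all-zero spectrum")
    return float(a @ b / (na * nb))


@dataclass
class ExposureFit:
    weights: np.ndarray | None
    residual_cosine: float
    n_variants: int
    eligible: bool


def fit_exposures(spectrum, signatures) -> ExposureFit:
    """Non-negative least-squares exposures of one spectrum on known
    signatures.

    ``signatures`` is a 192 x k column-stochastic matrix.  Regions with 20
    or fewer variants are refused (flagged ineligible, no weights), matching
    the eligibility rule used throughout the signature analyses.  Weights
    are rescaled to sum to at most 1; the cosine between the reconstruction
    and the observed spectrum is reported.
    """
    x = np.asarray(spectrum, dtype=float).ravel()
    S = np.asarray(signatures, dtype=float)
    if S.ndim != 2 or S.shape[0] != x.size:
        raise ValueError("signatures must be (n_channels, k)")
    total = x.sum()
    if total <= MIN_VARIANTS_FOR_EXPOSURE:
        return ExposureFit(None, float("nan"), int(total), eligible=False)
    xn = x / total
    w, _ = nnls(S, xn)
    if w.sum() > 1.0:
        w = w / w.sum()
    recon = S @ w
    res_cos = cosine_similarity(recon, xn) if recon.sum() > 0 else 0.0
    return ExposureFit(w, res_cos, int(total), eligible=True)


def extract_signatures(spectra, k: int, seed: int = 0,
                       max_iter: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """De novo signature extraction by seeded non-negative matrix
    factorisation.

    ``spectra`` is (n_samples, 192).  Returns ``(signatures, exposures)``
    where signatures is 192 x k column-stochastic and exposures is
    n_samples x k, with ``exposures @ signatures.T`` approximating the
    normalised input.  Deterministic for a fixed seed (NNDSVD-a init).
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2:
        raise ValueError("spectra must be 2-d (samples x channels)")
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of samples")
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("all-zero spectrum in input")
    Xn = X / totals[:, None]
    model = NMF(n_components=k, init="nndsvda", random_state=seed,
                max_iter=max_iter, tol=1e-8)
    W = model.fit_transform(Xn)          # samples x k
    H = model.components_                # k x channels
    col_sums = H.sum(axis=1)
    col_sums[col_sums == 0] = 1.0
    signatures = (H / col_sums[:, None]).T   # channels x k, column-stochastic
    exposures = W * col_sums[None, :]
    return signatures, exposures


def signature_ith(region_exposures, cohort_mean) -> np.ndarray:
    """Per-signature intratumour heterogeneity: the standard deviation of a
    signature's exposure across the regions of one tumour divided by the
    signature's mean exposure across the cohort.  Undefined (NaN) when the
    cohort mean is zero.
    """
    E = np.asarray(region_exposures, dtype=float)
    if E.ndim != 2 or E.shape[0] < 2:
        raise ValueError("need exposures for >= 2 regions (regions x k)")
    mu = np.asarray(cohort_mean, dtype=float)
    sd = E.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mu > 0, sd / mu, np.nan)
    return out
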