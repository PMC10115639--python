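"""Seeded synthetic multiregion cohorts with known ground truth.

The generators emulate the statistical structure the analysis stages assume:

* multiregion tumours with per-region purity and integer allele-specific
  copy-number states per gene (shared across the regions of a tumour);
* heterozygous SNPs whose RNA allele counts are beta-binomially
  overdispersed (sigma = 0.05 by default) around the admixture-weighted
  expected allelic ratio, with configurable true-ASE states (imprinting,
  nonsense-mediated decay, other copy-number-independent skew);
* negative-binomial expression counts with lognormal tumour-level random
  effects and per-region gene perturbations;
* RNA substitutions drawn from known 192-channel signature mixtures over a
  synthetic transcriptome, with optional decoy variants each designed to
  fail exactly one filter of the variant-filter stage.

Counts are simulated directly (no read-level simulation).  Every generator
is deterministic given the cohort seed; truth tables are exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signatures import CHANNELS, parse_channel
from .variants import revcomp


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


def _as_range(value) -> tuple[int, int]:
    if isinstance(value, int):
        return value, value
    lo, hi = int(value[0]), int(value[1])
    if lo > hi or lo < 1:
        raise ConfigurationError(f"invalid count range {value!r}")
    return lo, hi


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Cohort scaffold parameters.

    ``rna_overdispersion`` is the beta-binomial sigma of the RNA allele
    counts (default 0.05, the cohort-level overdispersion used by the ASE
    tests); ``purity_range`` the uniform sampling interval of per-region
    tumour purity.
    """
    n_tumours: int = 10
    regions_per_tumour: int | tuple[int, int] = (2, 4)
    n_genes: int = 200
    snps_per_gene: int | tuple[int, int] = (1, 3)
    purity_range: tuple[float, float] = (0.3, 0.8)
    rna_overdispersion: float = 0.05
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("purity_range must lie within (0, 1]")
        if not 0.0 <= self.rna_overdispersion < 1.0:
            raise ConfigurationError("rna_overdispersion must lie in [0, 1)")
        if min(self.n_tumours, self.n_genes) < 1:
            raise ConfigurationError("counts must be >= 1")
        _as_range(self.regions_per_tumour)
        _as_range(self.snps_per_gene)


@dataclass
class AseTruthConfig:
    """True-ASE composition of a simulated cohort.

    Fractions of genes given copy-number-independent allelic skew through
    imprinting, truncating-mutation NMD or other mechanisms; the skewed
    allele is expressed at ``ase_allelic_ratio`` of tumour transcripts.
    """
    frac_cn_indep_ase: float = 0.05
    frac_imprinted: float = 0.0
    frac_truncating_nmd: float = 0.0
    ase_allelic_ratio: float = 0.9

    def __post_init__(self):
        for f in (self.frac_cn_indep_ase, self.frac_imprinted,
                  self.frac_truncating_nmd):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        if not 0.5 < self.ase_allelic_ratio <= 1.0:
            raise ConfigurationError("ase_allelic_ratio must lie in (0.5, 1]")


@dataclass
class ExpressionConfig:
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 1.0
    tumour_sigma: float = 0.5       # lognormal sd of tumour random effect
    region_sigma: float = 1.0       # lognormal sd of region perturbations
    frac_perturbed: float = 0.1     # genes perturbed per region
    nb_size: float = 10.0           # negative-binomial dispersion (size)


@dataclass
class SignatureTruth:
    """Known signatures and per-region exposures for variant simulation."""
    signature_matrix: np.ndarray          # 192 x k, column-stochastic
    exposures_per_region: np.ndarray      # n_regions x k, rows sum to 1
    variants_per_region: int = 500

    def __post_init__(self):
        S = np.asarray(self.signature_matrix, dtype=float)
        E = np.asarray(self.exposures_per_region, dtype=float)
        if S.ndim != 2 or S.shape[0] != len(CHANNELS):
            raise ConfigurationError("signature_matrix must be 192 x k")
        if np.any(S < 0) or not np.allclose(S.sum(axis=0), 1.0):
            raise ConfigurationError("signature columns must be stochastic")
        if E.ndim != 2 or E.shape[1] != S.shape[1]:
            raise ConfigurationError("exposures must be n_regions x k")
        if np.any(E < 0) or not np.allclose(E.sum(axis=1), 1.0):
            raise ConfigurationError("exposure rows must sum to 1")
        if self.variants_per_region < 1:
            raise ConfigurationError("variants_per_region must be >= 1")
        self.signature_matrix = S
        self.exposures_per_region = E


# allele-specific CN states and their frequencies: a chromosomally unstable
# NSCLC-like mixture with frequent LOH and gains
CN_STATES = [((1, 1), 0.40), ((2, 1), 0.20), ((2, 2), 0.12), ((1, 0), 0.10),
             ((2, 0), 0.08), ((3, 1), 0.06), ((3, 2), 0.04)]

_STAGE_COHORT, _STAGE_ASE, _STAGE_EXPR, _STAGE_RNA, _STAGE_TX = range(5)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2 ** 31), stage])


@dataclass
class Cohort:
    config: CohortConfig
    regions: pd.DataFrame       # tumour_id, region_id, purity
    copy_number: pd.DataFrame   # tumour_id, gene_id, major_cn, minor_cn
    genes: list[str] = field(default_factory=list)


def generate_cohort(config: CohortConfig, cn_states=None) -> Cohort:
    """Draw the cohort scaffold: regions with purity and one allele-specific
    CN state per (tumour, gene), with major >= minor >= 0 and not both 0."""
    rng = _rng(config.seed, _STAGE_COHORT)
    states, weights = zip(*(cn_states or CN_STATES))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    r_lo, r_hi = _as_range(config.regions_per_tumour)

    region_rows, cn_rows = [], []
    for ti in range(config.n_tumours):
        tumour = f"T{ti:03d}"
        n_regions = int(rng.integers(r_lo, r_hi + 1))
        purities = rng.uniform(config.purity_range[0], config.purity_range[1],
                               size=n_regions)
        for ri in range(n_regions):
            region_rows.append((tumour, f"{tumour}_R{ri + 1}", float(purities[ri])))
        state_idx = rng.choice(len(states), size=config.n_genes, p=weights)
        for g, si in zip(genes, state_idx):
            major, minor = states[si]
            cn_rows.append((tumour, g, major, minor))
    return Cohort(
        config=config,
        regions=pd.DataFrame(region_rows, columns=["tumour_id", "region_id", "purity"]),
        copy_number=pd.DataFrame(cn_rows, columns=["tumour_id", "gene_id",
                                                   "major_cn", "minor_cn"]),
        genes=genes,
    )


# ---------------------------------------------------------------------------
# ASE counts
# ---------------------------------------------------------------------------

def _nb_depth(rng, mean, size, n):
    """Negative-binomial depths with the given mean, truncated at >= 1."""
    p = size / (size + mean)
    return np.maximum(1, rng.negative_binomial(size, p, size=n))


def _betabin_draw(rng, q, t, sigma):
    """Beta-binomial count with mean fraction q, trials t, correlation
    sigma; sigma = 0 is exactly binomial."""
    q = np.clip(q, 1e-4, 1.0 - 1e-4)
    if sigma == 0.0:
        return rng.binomial(t, q)
    a = q * (1.0 - sigma) / sigma
    b = (1.0 - q) * (1.0 - sigma) / sigma
    return rng.binomial(t, rng.beta(a, b))


def transcript_fraction(purity: float, expression_factor: float = 1.0) -> float:
    """Tumour transcript fraction implied by DNA purity when tumour cells
    express ``expression_factor`` times more per chromosome copy than
    non-tumour cells."""
    return expression_factor * purity / (expression_factor * purity + (1.0 - purity))


def simulate_ase_counts(cohort: Cohort, ase_cfg: AseTruthConfig,
                        depth_mean: float = 30.0, dna_depth_mean: float = 100.0,
                        tumour_expression_factor: float = 1.0,
                        nb_size: float = 10.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-SNP DNA/RNA allele counts plus an exhaustive truth table.

    Returns ``(snps, truth)``.  ``truth`` has one row per (tumour, gene)
    with ``true_class`` in {none, cn_dep, cn_indep}, the driving mechanism
    and the haplotype favoured by any CN-independent skew.  The RNA
    major-allele counts are beta-binomial with the cohort overdispersion
    sigma around the admixture-weighted expected allelic ratio; true-ASE
    genes are shifted toward ``ase_allelic_ratio`` within tumour
    transcripts.
    """
    if depth_mean <= 0 or dna_depth_mean <= 0:
        raise ConfigurationError("depth means must be positive")
    cfg = cohort.config
    sigma = cfg.rna_overdispersion
    rng = _rng(cfg.seed, _STAGE_ASE)
    s_lo, s_hi = _as_range(cfg.snps_per_gene)
    genes = cohort.genes
    n_genes = len(genes)

    # imprinted genes are a cohort-wide property; NMD and other CN-independent
    # skew are tumour-level events
    n_imp = int(round(ase_cfg.frac_imprinted * n_genes))
    imprinted = set(rng.choice(genes, size=n_imp, replace=False)) if n_imp else set()

    cn_lookup = cohort.copy_number.set_index(["tumour_id", "gene_id"])
    snp_rows, truth_rows = [], []
    for tumour, regions in cohort.regions.groupby("tumour_id", sort=False):
        free = [g for g in genes if g not in imprinted]
        n_ci = int(round(ase_cfg.frac_cn_indep_ase * n_genes))
        n_nmd = int(round(ase_cfg.frac_truncating_nmd * n_genes))
        pick = list(rng.choice(free, size=min(n_ci + n_nmd, len(free)),
                               replace=False))
        other_ci, nmd = set(pick[:n_ci]), set(pick[n_ci:])

        for gi, gene in enumerate(genes):
            nA, nB = cn_lookup.loc[(tumour, gene)]
            nA, nB = int(nA), int(nB)
            if gene in imprinted:
                mech = "imprinted"
            elif gene in nmd:
                mech = "truncating_nmd"
            elif gene in other_ci:
                mech = "other"
            else:
                mech = "cn" if nA != nB else "none"
            cn_indep = mech in ("imprinted", "truncating_nmd", "other")
            true_class = "cn_indep" if cn_indep else ("cn_dep" if nA != nB else "none")
            ase_hap = int(rng.integers(1, 3)) if cn_indep else 0
            truth_rows.append((tumour, gene, true_class, mech,
                               ase_hap if cn_indep else np.nan))

            n_snps = int(rng.integers(s_lo, s_hi + 1))
            ref_is_A = rng.random(n_snps) < 0.5  # phase of the reference allele
            positions = [gi * 10_000 + 100 * (k + 1) for k in range(n_snps)]

            for _, region in regions.iterrows():
                pi = region["purity"]
                pi_tx = transcript_fraction(pi, tumour_expression_factor)
                dna_baf_A = (pi * nA + (1 - pi)) / (pi * (nA + nB) + 2 * (1 - pi))
                if cn_indep:
                    # the skew affects all cell populations (as with genomic
                    # imprinting): the bulk allelic mean is the ratio itself
                    r = ase_cfg.ase_allelic_ratio
                    q_A = r if ase_hap == 1 else 1.0 - r
                else:
                    q_A = (pi_tx * nA + (1 - pi_tx)) / (pi_tx * (nA + nB) + 2 * (1 - pi_tx))

                for k in range(n_snps):
                    d_tot = int(_nb_depth(rng, dna_depth_mean, nb_size, 1)[0])
                    d_A = int(rng.binomial(d_tot, np.clip(dna_baf_A, 1e-4, 1 - 1e-4)))
                    r_tot = int(_nb_depth(rng, depth_mean, nb_size, 1)[0])
                    r_A = int(_betabin_draw(rng, q_A, r_tot, sigma))
                    d_B, r_B = d_tot - d_A, r_tot - r_A
                    tie = d_A == d_B
                    # DNA-read-designated major allele; ties go to the reference
                    major_is_A = d_A > d_B or (tie and bool(ref_is_A[k]))
                    if major_is_A:
                        dmaj, dmin, rmaj, rmin = d_A, d_B, r_A, r_B
                        mcn, ncn = nA, nB
                    else:
                        dmaj, dmin, rmaj, rmin = d_B, d_A, r_B, r_A
                        mcn, ncn = nB, nA
                    snp_rows.append((
                        f"{gene}_s{k}", gene, tumour, region["region_id"],
                        "chr1", positions[k], gene, dmaj, dmin, rmaj, rmin,
                        mcn, ncn, major_is_A == bool(ref_is_A[k]),
                        major_is_A, tie))
    snps = pd.DataFrame(snp_rows, columns=[
        "snp_id", "gene_id", "tumour_id", "region_id", "chrom", "pos",
        "phase_block_id", "dna_major_count", "dna_minor_count",
        "rna_major_count", "rna_minor_count", "major_cn", "minor_cn",
        "major_is_reference", "major_is_hap1", "dna_tie"])
    truth = pd.DataFrame(truth_rows, columns=[
        "tumour_id", "gene_id", "true_class", "mechanism", "ase_hap"])
    return snps, truth


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_expression(cohort: Cohort, expr_cfg: ExpressionConfig | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Negative-binomial gene x region counts with shared tumour effects.

    Counts ~ NB(mean = baseline_g * tumour_effect_{t,g} * region_factor,
    size = nb_size); per region a random ``frac_perturbed`` subset of genes
    receives a lognormal perturbation factor.  Regions of a tumour share
    the tumour effect and are therefore more correlated with each other
    than with regions of other tumours.  Returns ``(counts, truth)`` where
    truth records the tumour effects and each region's perturbed gene set.
    """
    cfg = expr_cfg or ExpressionConfig()
    rng = _rng(cohort.config.seed, _STAGE_EXPR)
    genes = cohort.genes
    n_genes = len(genes)
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, n_genes)

    counts = {}
    tumour_effects = {}
    perturbed_sets = {}
    for tumour, regions in cohort.regions.groupby("tumour_id", sort=False):
        effect = rng.lognormal(0.0, cfg.tumour_sigma, n_genes)
        tumour_effects[tumour] = effect
        for _, region in regions.iterrows():
            factor = np.ones(n_genes)
            n_pert = int(round(cfg.frac_perturbed * n_genes))
            idx = rng.choice(n_genes, size=n_pert, replace=False) if n_pert else []
            if len(idx):
                factor[idx] = rng.lognormal(0.0, cfg.region_sigma, n_pert)
            mean = baseline * effect * factor
            p = cfg.nb_size / (cfg.nb_size + mean)
            counts[region["region_id"]] = rng.negative_binomial(cfg.nb_size, p)
            perturbed_sets[region["region_id"]] = [genes[i] for i in idx]
    mat = pd.DataFrame(counts, index=genes)
    truth = {"baseline": pd.Series(baseline, index=genes),
             "tumour_effects": {t: pd.Series(e, index=genes)
                                for t, e in tumour_effects.items()},
             "perturbed_genes": perturbed_sets}
    return mat, truth


# ---------------------------------------------------------------------------
# synthetic transcriptome and RNA variants
# ---------------------------------------------------------------------------

@dataclass
class Transcriptome:
    records: list[tuple[str, str, str]]  # (name, sequence, strand)

    def sequences(self) -> dict[str, str]:
        return {name: seq for name, seq, _ in self.records}

    def strands(self) -> pd.DataFrame:
        return pd.DataFrame([(n, s) for n, _, s in self.records],
                            columns=["transcript", "strand"])


def synthetic_transcriptome(n_transcripts: int = 30, length: int = 2000,
                            seed: int = 0) -> Transcriptome:
    """Random uniform-composition transcript sequences with alternating
    annotated strands."""
    rng = _rng(seed, _STAGE_TX)
    records = []
    for i in range(n_transcripts):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        records.append((f"tx{i:03d}", seq, "+" if i % 2 == 0 else "-"))
    return Transcriptome(records)


def _context_index(tx: Transcriptome):
    """Map mRNA-sense trinucleotide -> list of (transcript index, 0-based
    genomic position) over transcript interiors (4-base flanks available)."""
    index: dict[str, list[tuple[int, int]]] = {}
    for ti, (_, seq, strand) in enumerate(tx.records):
        for i in range(4, len(seq) - 4):
            up, ref, down = seq[i - 1], seq[i], seq[i + 1]
            if strand == "-":
                up, ref, down = revcomp(down), revcomp(ref), revcomp(up)
            index.setdefault(up + ref + down, []).append((ti, i))
    return index


_DECOY_RULES = ["low_rna_coverage", "low_alt_support", "low_vaf",
                "low_germline_dna", "low_tumour_dna", "dna_support",
                "homopolymer_flank", "blacklist"]


def default_blacklist(tx: Transcriptome) -> pd.DataFrame:
    """One blacklisted interval (0-based half-open) on the first transcript."""
    name, seq, _ = tx.records[0]
    end = min(300, len(seq))
    return pd.DataFrame([(name, 100, end)], columns=["chrom", "start", "end"])


def _clean_depths(rng):
    rna_depth = int(10 + _nb_depth(rng, 40, 10, 1)[0])
    vaf = rng.uniform(0.05, 0.6)
    rna_alt = int(np.clip(rng.binomial(rna_depth, vaf), 3, rna_depth))
    return {"rna_depth": rna_depth, "rna_alt": rna_alt,
            "dna_germline_depth": int(30 + rng.poisson(70)),
            "dna_tumour_depth_total": int(30 + rng.poisson(170)),
            "dna_alt_support": 0, "dna_error_support": int(rng.poisson(0.5))}


def _decoy_depths(rule, rng):
    d = _clean_depths(rng)
    if rule == "low_rna_coverage":
        d.update(rna_depth=9, rna_alt=3)
    elif rule == "low_alt_support":
        d.update(rna_depth=50, rna_alt=2)
    elif rule == "low_vaf":
        d.update(rna_depth=1000, rna_alt=9)
    elif rule == "low_germline_dna":
        d.update(dna_germline_depth=29)
    elif rule == "low_tumour_dna":
        d.update(dna_tumour_depth_total=29)
    elif rule == "dna_support":
        d.update(dna_tumour_depth_total=200, dna_alt_support=8,
                 dna_error_support=0)
    return d


def simulate_rna_variants(cohort: Cohort, truth: SignatureTruth,
                          transcriptome: Transcriptome,
                          decoy_fractions: dict[str, float] | None = None,
                          blacklist: pd.DataFrame | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place RNA substitutions drawn from per-region signature mixtures.

    Each variant is placed at a transcriptome position whose strand-aware
    trinucleotide context matches the channel sampled from the region's
    exposure mixture; depth annotations are drawn so the variant passes
    every filter.  ``decoy_fractions`` maps filter-rule names to fractions
    of additional variants designed to fail exactly that rule.  Returns
    ``(variants, exposure_truth)``.

    Raises :class:`GenerationError` naming the channel when a requested
    context is absent from the transcriptome.
    """
    rng = _rng(cohort.config.seed, _STAGE_RNA)
    decoy_fractions = decoy_fractions or {}
    unknown = set(decoy_fractions) - set(_DECOY_RULES)
    if unknown:
        raise ConfigurationError(f"unknown decoy rules: {sorted(unknown)}")
    ctx_index = _context_index(transcriptome)
    if blacklist is None and decoy_fractions.get("blacklist"):
        blacklist = default_blacklist(transcriptome)
    bl_by_chrom = {}
    if blacklist is not None:
        for chrom, grp in blacklist.groupby("chrom"):
            bl_by_chrom[chrom] = grp[["start", "end"]].to_numpy(np.int64)

    def in_blacklist(chrom, pos0):
        for start, end in bl_by_chrom.get(chrom, ()):
            if start <= pos0 < end:
                return True
        return False

    # homopolymer-flank candidate positions for decoys
    homo_positions = []
    for ti, (_, seq, _) in enumerate(transcriptome.records):
        for i in range(4, len(seq) - 4):
            if seq[i - 4:i] == seq[i] * 4:
                homo_positions.append((ti, i))

    S = truth.signature_matrix
    E = truth.exposures_per_region
    regions = cohort.regions["region_id"].tolist()
    if E.shape[0] != len(regions):
        raise ConfigurationError("exposures_per_region rows must match the "
                                 "cohort's region count")

    rows = []
    for r_idx, region in enumerate(regions):
        tumour = cohort.regions.iloc[r_idx]["tumour_id"]
        mixture = S @ E[r_idx]
        mixture = mixture / mixture.sum()
        ch_idx = rng.choice(len(CHANNELS), size=truth.variants_per_region,
                            p=mixture)
        for ci in ch_idx:
            up, ref_m, alt_m, down = parse_channel(CHANNELS[ci])
            candidates = ctx_index.get(up + ref_m + down)
            if not candidates:
                raise GenerationError(
                    f"no transcriptome position provides context for channel "
                    f"{CHANNELS[ci]}")
            for _ in range(50):
                ti, i = candidates[rng.integers(len(candidates))]
                name, seq, strand = transcriptome.records[ti]
                ref = ref_m if strand == "+" else revcomp(ref_m)
                alt = alt_m if strand == "+" else revcomp(alt_m)
                c5, c3 = seq[i - 4:i], seq[i + 1:i + 5]
                if in_blacklist(name, i):
                    continue
                if c5 in {ref * 4, alt * 4} or c3 in {ref * 4, alt * 4}:
                    continue
                break
            else:
                raise GenerationError(
                    f"could not place a clean variant for channel {CHANNELS[ci]}")
            rows.append({
                "chrom": name, "pos": i + 1, "ref": ref, "alt": alt,
                "transcript_strand": strand, "context5": c5, "context3": c3,
                "up": seq[i - 1], "down": seq[i + 1],
                **_clean_depths(rng),
                "region_id": region, "tumour_id": tumour,
                "truth_channel": CHANNELS[ci], "is_decoy": False,
                "decoy_rule": ""})

        all_positions = [pos for cands in ctx_index.values() for pos in cands]
        for rule, frac in decoy_fractions.items():
            n_decoys = int(round(frac * truth.variants_per_region))
            for _ in range(n_decoys):
                for _attempt in range(100):
                    if rule == "homopolymer_flank":
                        if not homo_positions:
                            raise GenerationError(
                                "no homopolymer-flanked position in the "
                                "transcriptome")
                        ti, i = homo_positions[rng.integers(len(homo_positions))]
                    elif rule == "blacklist":
                        name0, start, end = blacklist.iloc[0]
                        ti = next(k for k, rec in enumerate(transcriptome.records)
                                  if rec[0] == name0)
                        seq0 = transcriptome.records[ti][1]
                        i = int(rng.integers(max(start, 4),
                                             min(end, len(seq0) - 4)))
                    else:
                        ti, i = all_positions[rng.integers(len(all_positions))]
                    name, seq, strand = transcriptome.records[ti]
                    ref = seq[i]
                    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                    c5, c3 = seq[i - 4:i], seq[i + 1:i + 5]
                    # the decoy must fail exactly its designed rule
                    homo = c5 in {ref * 4, alt * 4} or c3 in {ref * 4, alt * 4}
                    listed = in_blacklist(name, i)
                    if rule == "homopolymer_flank" and listed:
                        continue
                    if rule == "blacklist" and homo:
                        continue
                    if rule not in ("homopolymer_flank", "blacklist") \
                            and (homo or listed):
                        continue
                    break
                else:
                    raise GenerationError(f"could not place a {rule} decoy")
                rows.append({
                    "chrom": name, "pos": i + 1, "ref": ref, "alt": alt,
                    "transcript_strand": strand, "context5": c5, "context3": c3,
                    "up": seq[i - 1], "down": seq[i + 1],
                    **_decoy_depths(rule, rng),
                    "region_id": region, "tumour_id": tumour,
                    "truth_channel": "", "is_decoy": True, "decoy_rule": rule})

    variants = pd.DataFrame(rows)
    exposure_truth = pd.DataFrame(
        E, columns=[f"sig{j + 1}" for j in range(E.shape[1])])
    exposure_truth.insert(0, "region_id", regions)
    return variants, exposure_truth
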