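# Methods

This note documents the statistical models implemented in `txevo`, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions.  No
empirical claim is made here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Beta-binomial model of allelic counts

Allele-specific read counts are overdispersed relative to a binomial
because the per-site allelic fraction is itself variable (sampling,
mapping, library effects).  We model the major-allele count as
X | q ~ Binomial(t, q) with q ~ Beta(α, β), parameterised by the mean p
and the intra-class correlation ρ:

    α = p(1−ρ)/ρ,   β = (1−p)(1−ρ)/ρ,
    Var X = t·p·(1−p)·(1 + (t−1)ρ).

ρ = 0 degenerates continuously to the binomial, which is why this
parameterisation was chosen over (α, β) or (μ, φ) forms; the cohort-level
overdispersion default is ρ = 0.05 everywhere (tests and generator
alike).  Tails are computed with `scipy.stats.betabinom`; the test suite
checks them against an independent log-beta pmf summation to 1e-10 up to
t = 500.  The deviation from the binomial is O(ρ) in sup-norm (about
1.2e-5 at ρ = 1e-6, t = 100), so "convergence" tests assert linear
shrinkage rather than a fixed small gap.

## ASE testing, combination and classification

Per SNP with coverage t > 8 (strict), three one-tailed beta-binomial
tests are computed (against 0.5 upward, 0.5 downward, and the copy-number
ratio upward) plus the independent filter CPNratio^t < 0.001, which
removes low-coverage sites and extreme CN ratios.  Conventions:

* The *major* allele is the one with more reads in matched DNA; a DNA
  tie designates the reference allele as major and sets a tie flag
  (deterministic and auditable).
* CPNratio ∈ {0, 1} (LOH) leaves test 4 undefined; such SNPs are removed
  — CPNratio = 1 already fails the filter (1^t = 1), CPNratio = 0 is
  inconsistent with expressed heterozygosity.
* Fisher combination clips p-values at 1e-300 before the log (numerical
  floor; does not change ranking); statistic −2Σln p on 2k df.
* The per-SNP minimum of tests 3 and 4 enters combination B uncorrected
  for the implicit two-test selection, as the procedure is defined; this
  makes B slightly anti-conservative in principle, which the null-cohort
  error-control test bounds in practice.
* Benjamini–Hochberg runs within each sample (tumour region) across
  genes, separately for A and B; no cross-sample pooling.
* Genes with SNPs in several phase blocks are combined regardless of
  block; only MSAI restricts itself to within-block comparisons.

Labels partition evaluable genes: FDR_B < 0.05 → CN-independent ASE;
else FDR_A < 0.05 → CN-dependent ASE; else biallelic.

ITH of CN-independent ASE follows the homogeneous-fraction definition:
among genes with events in ≥ 2 regions, the fraction also detected in
*every* evaluable region (≥ 2 required), reported as 1 − that fraction.
(The looser "detected in only a subset of regions" phrasing disagrees
with this formula for genes with exactly one event; the formula is
implemented.)

Enrichment odds ratios use the sample cross-product with a Haldane 0.5
correction on zero cells and a Fisher exact p on the raw table.

### Promoter ASM rule

A CpG is an ASM locus iff its 99% highest-density methylation interval
lies within [0.15, 0.75] *and* its point estimate within [0.2, 0.7]
(intermediate pure-tumour methylation as a proxy for allelic
methylation); a promoter is ASM iff ≥ 3 consecutive loci qualify.

### MSAI

Mirrored subclonal allelic imbalance requires phased input: each SNP
carries a `major_is_hap1` flag linking its DNA-major allele to a
haplotype of its phase block.  Per region, haplotype DNA reads are
pooled; imbalance is a two-sided binomial test at α = 0.05.  *Genomic*
MSAI: two imbalanced regions with different major haplotypes.
*Genomic–transcriptomic* MSAI: a region without DNA imbalance called
CN-independent ASE whose RNA-favoured haplotype is the one depleted in
another, imbalanced region.  The α and the pooled-read construction are
package choices; unphased genes are skipped with a log notice.

## I-TED

Median-of-ratios normalisation (reference set: genes nonzero in all
regions), expressed-gene filter (> 5 reads in ≥ 20% of regions, strict),
log2(x+1) transform, top-500 variable genes by variance across the cohort
with ties broken by gene identifier, then per-region mean of
1 − distance-correlation against same-tumour regions and per-tumour
median.  Notes:

* log2(x+1) stands in for a variance-stabilising transformation, which is
  library-specific; the transform is a pluggable argument.  The +1
  pseudocount leaves a small residual global-scale sensitivity (and
  variable-gene reselection a larger one), so scale invariance holds to
  ~2% rather than machine precision.
* Distance correlation is the biased V-statistic (double-centred
  absolute-difference matrices); constant vectors are degenerate and
  return NaN.  The `dcor` package is not a dependency; the ~15-line
  implementation is verified against an explicit-loop oracle.
* Single-region tumours are flagged, not computed.

## Tumour transcript fraction

Non-tumour cells are fixed at diploid with equal per-copy expression;
tumour cells contribute their allele-specific copy numbers.  The expected
major-allele RNA fraction in a segment (n_A, n_B) at transcript fraction
ρ is (ρ·n_A + 1 − ρ) / (ρ·(n_A+n_B) + 2(1−ρ)).  BAFs are *oriented to
the DNA-major allele* (known from the allele-specific CN input) rather
than folded at max(b, 1−b), which would bias the fit upward near balanced
BAFs; ρ is a least-squares grid search on [0, 1] with step 0.001, ties to
the smaller ρ, flagged unidentifiable when every segment is balanced.
ASCAT's full segmentation/ploidy search is out of scope.  When tumour
cells express more per chromosome copy than normal cells the transcript
fraction exceeds DNA purity — `simulate.transcript_fraction(purity,
expression_factor)` makes this relationship explicit and the test suite
asserts it on generator truth.

## RNA-variant filters and spectra

Filter thresholds (germline DNA ≥ 30, tumour DNA ≥ 30, RNA depth ≥ 10,
alt reads ≥ 3, VAF ≥ 1% — exactly 1% passes) are recorded as independent
named flags, so the engine is order-independent and a variant passes iff
unflagged.  The DNA-noise rule is one concrete reading of "alt support
vs. other-error support against total coverage": a one-tailed Fisher test
on [[alt, depth−alt], [err, depth−err]], excluding at p < 0.1; it is
isolated behind a single function.  Note the boundary case (5 alt, 1
error, depth 1000) gives p ≈ 0.109 and is therefore *kept* — the
threshold is strict.

Spectra use 192 strand-aware channels ordered lexicographically by
(ref, alt, 5′ base, 3′ base); there is no community standard for
192-channel RNA spectra, so the order is emitted with every output.
Minus-strand variants are reverse-complemented (base and context) so
channels are mRNA-sense; the opposite-strand channel map is an involution.
Exposure fitting is plain NNLS on the normalised spectrum (deterministic
and oracle-checkable; no iterative signature dropping), refused for
regions with ≤ 20 variants; no trinucleotide-abundance renormalisation is
applied.  De novo extraction is seeded NMF (NNDSVD-a initialisation) as a
deterministic stand-in for hierarchical Dirichlet process samplers.
Signature ITH is the sample standard deviation of a signature's exposure
across regions divided by its cohort mean exposure.

### Hairpins and motif enrichment

A hairpin is called when a 3–5-base loop containing the variant has
≥ 3 immediately flanking bases pairing 5′-stem to 3′-stem (reverse
complement); the detector is validated against exhaustive pairing
enumeration.  APOBEC motif enrichment tests, per C>T site (G>A on the
genomic minus strand), whether the *other* C>T events within ±20 nt fall
on CAT-context cytosines more often than the window's C/G opportunity
positions predict, by a one-tailed Fisher test, with a pooled cohort
table alongside.  Because the opportunity margin of a ±20 nt window is
only ~20 positions, the exact conditional test is strongly discrete and
conservative: with each variant at a distinct position the most extreme
attainable table does not reach p ≤ 0.05 at all, and even with recurrent
events the null rejection rate is far below nominal.  The per-site test
is therefore valid but low-powered by construction; inference should lean
on the pooled table, whose margins are large.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume —
not real data.  Defaults: 10 tumours, 2–4 regions each, purity uniform on
(0.3, 0.8), 200 genes with 1–3 heterozygous SNPs, allele-specific CN per
(tumour, gene) from a chromosomally unstable mixture
{(1,1): 0.40, (2,1): 0.20, (2,2): 0.12, (1,0): 0.10, (2,0): 0.08,
(3,1): 0.06, (3,2): 0.04}, DNA depth NB(mean 100), RNA depth NB(mean 30,
size 10, truncated ≥ 1 — the depth distribution is not specified by any
source, so it is configurable rather than calibrated), RNA allele counts
beta-binomial with σ = 0.05.  Null genes draw their allelic mean from the
purity-admixed copy-number expectation, which lies between 0.5 and
CPNratio, so the three tests are conservative on them.  True
CN-independent genes (imprinted / NMD / other, configurable fractions)
receive a bulk allelic mean equal to `ase_allelic_ratio` (default 0.9)
directly — imprinting skews normal and tumour cells alike — toward a
randomly chosen haplotype.  Expression counts are NB(size 10) around
baseline × lognormal tumour effect × per-region perturbations of a random
10% gene subset.  RNA variants are placed at transcriptome positions whose
mRNA-sense trinucleotide matches the channel drawn from the region's
signature mixture; decoys are labelled with the single filter rule they
are built to fail, making filter tests one-to-one.  The synthetic
transcriptome is uniform-composition random sequence with alternating
strands and a sidecar strand table; a 60 kb default comfortably contains
all 64 contexts and homopolymer runs.

What a green test does **not** establish: performance on real data with
mapping bias, genotyping error, CN-segmentation error, non-uniform SNP
density, context-dependent sequencing error, or overlapping antisense
transcription — none of which are emulated.

All generators are deterministic given the cohort seed (per-stage child
generators derived from it; seeds are reduced mod 2^31), truth tables are
exhaustive, and every artefact round-trips through the package readers.

## Known limitations

* The Eq.-B combination is uncorrected for min-of-two-tests selection
  (bounded empirically by the null-cohort test).
* The transcript-fraction model assumes equal per-copy expression within
  the tumour and diploid normal cells; subclonal CN is not modelled.
* The per-site motif test is structurally conservative (see above).
* MSAI detection assumes correct phasing and uses a simple pooled
  binomial imbalance rule; it flags candidates rather than proving
  parallel evolution.
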