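# Methods

## The association model

Expression is treated as a continuous trait; every genetic model is an
ordinary-least-squares fit against a coding of the genotype dosage
g ∈ {0, 1, 2} (alt-allele count). ADD, DOM and REC are simple
regressions with a two-sided t-test on the slope (df = n−2). GENO_2DF
and DOMDEV share one joint fit y ~ 1 + g + het with het = 1[g = 1]:
GENO_2DF is the 2-df F-test of both genetic coefficients (equivalent to
a genotype-as-factor test), DOMDEV the t-test of the het coefficient
(deviation from additivity), both with residual df = n−3. The fits are
computed from centered cross-products in closed form; a vectorized path
(`association.batch_min_p`) evaluates all five models for a block of
variants against one expression vector at once and is verified against
the scalar path to 1e-10 in the test suite.

Missing genotypes (including half-calls) and non-finite expression
values are dropped pairwise per variant–probe pair — this maximizes n
and is standard practice. A model is reported NA when its design is
degenerate: constant predictor (e.g. REC with no homozygous-alt
carriers), no heterozygotes (het constant, so GENO_2DF/DOMDEV are
rank-deficient), only two genotype classes {0, 1} (g and het collinear),
constant expression, or n below the df requirement. Rank deficiency is
detected on the centered 2×2 normal-equation determinant with a relative
tolerance of 1e-10.

The eQTL score of a (variant, probe, population) triple is the smallest
non-NA p-value across the five models (min-P). Ties are broken by the
fixed order ADD < GENO_2DF < DOMDEV < DOM < REC so outputs are
reproducible. No multiple-testing correction is applied to min-P; the
inflation from taking a minimum over five correlated tests is
characterized empirically by the permutation module instead (measured
exceedance at α = 10⁻⁴ is ≈ 2.5–3.5×α, inside the Bonferroni band
[α, 5α]).

## Windows, cutoffs, sharing, peaks

The cis window is anchored to the gene span: a variant pairs with a gene
iff pos ∈ [start − w, end + w] (closed interval), w = 200 kb by default;
a TSS-anchored mode (±w around the TSS) is available via
`anchor="tss"`. A cis-eQTL is a (variant, probe) pair — genes may carry
several probes, and gene-level views are derived, never primary. Two
cutoffs are used in different roles: 10⁻² for the database and the GWAS
intersection, 10⁻⁴ for distribution analyses; sharing is always
evaluated at the cutoff of the table being summarized. A pair passing in
≥ 2 populations is population-shared, in exactly one
population-specific. Peak reduction keeps one record per (probe,
population, variant class) — smallest min-P, ties to the smaller
position — so LD-driven redundancy does not inflate indel/SNP ratios;
it is idempotent.

Variant filters: biallelic records only (multiallelic VCF records are
skipped, not split, since splitting changes allele frequencies);
per-population folded MAF ≥ 1% and missing rate < 20% for the eQTL
panel, MAF ≥ 0.1% for the LD panel. MAF is computed on the selected
population's non-missing alleles. Coordinates are 1-based closed
internally (VCF convention); BED I/O converts at the boundary. Indel
position is the VCF anchor base; an indel's footprint for interval
overlap is POS through POS + len(ref) − 1.

An optional rank inverse-normal transform of expression is available
per probe (`inverse_normal=True`); the default is raw values, since the
scan's input is assumed to be already-normalized array intensities.

## Linkage disequilibrium

With phased haplotypes, the four two-locus haplotype frequencies are
counted directly; D = p_AB − p_A·p_B, r² = D²/(p_A(1−p_A)p_B(1−p_B)),
D′ = |D|/D_max with the usual frequency-dependent bound. D′ is reported
as an absolute value in [0, 1]; the sign of D is recoverable from the
frequencies. The denominator is grouped as (p_A(1−p_A))·(p_B(1−p_B)) so
that r² is bit-for-bit symmetric under swapping the two sites.

With unphased genotypes, haplotype frequencies are estimated by EM over
the double-heterozygote phase ambiguity (initialized at linkage
equilibrium, converged when the largest frequency change is < 1e-8,
capped at 1,000 iterations). The tests verify the EM fixed point
coincides with the global ML solution and that, on block-structured
haplotypes at n = 200 with MAF ≥ 0.05, mean |r²_EM − r²_phased| < 0.01.
When every individual is a double heterozygote the likelihood is
symmetric in phase and the result is flagged `ambiguous`. Phased
counting is always preferred when phase is available; EM is the
fallback for unphased input. EM assumes random mating within the
analyzed sample, so LD across pooled populations should be computed on
concatenated haplotypes (supported directly) rather than via EM on
pooled genotypes.

Proxy search interprets its 1,000 kb window as the total span (±500 kb
around the query); a flank interpretation (±window) is available via
`window_mode="flank"` since the phrase "a 1 Mb window" is genuinely
ambiguous. Taggers of GWAS eSNPs are computed per population and
aggregated by best r² in any population; pooled super-population
analyses use sample concatenation.

## Permutation null

Each permutation applies one joint shuffle of the expression sample
labels to all probes, so probe–probe covariance and genotype LD are both
preserved; only the genotype–phenotype link is broken. (A per-probe
independent shuffle — a weaker null — is available behind a flag.) The
full scan is rerun per permutation; records under the cutoff are pooled
as fake cis-eQTLs. Per-permutation counts first reduce to the best
record per variant (minimum across probes), so a variant cis to several
probes of one gene is counted once. Randomness flows from one master
seed through `SeedSequence.spawn` substreams, making runs byte-identical
given (seed, inputs).

## Genomic categories and enrichment

Variants map to exactly one of six mutually exclusive categories with
the fixed precedence TSS10K > UTR3 > EXON > NCRNA > INTRON > INTERGENIC
(configurable). The precedence puts the ±10 kb TSS flank first because
TSS proximity is the headline contrast; 3′UTR is separated from other
exonic sequence, 5′UTR folds into EXON, and EXON is restricted to coding
genes so the ncRNA slice stays distinct. The TSS distance is signed and
strand-aware (negative = upstream). Enrichment of real against fake
eQTLs is a 2×2 chi-squared without continuity correction (the intended
regime is large counts; Yates correction is behind a flag, and results
with an expected cell < 5 carry a warning flag). MAF contrasts use a
two-sample t-test (equal-variance default, Welch optional); indel/SNP
ratio contrasts across populations use a paired t-test by default, since
the same populations contribute one ratio to each group.

## The synthetic generator

The generator stands in for a sequenced multi-population LCL panel with
array expression. Defaults: six populations × 80 samples; 2,000 variants
(15% indels) on one chromosome spanning ~8 Mb; 80 genes (10 kb span,
alternating strand, every tenth non-coding) with 100 probes (20 genes
carry two probes); LD blocks of 8 variants at within-block target
r² = 0.8; per-variant base allele frequencies uniform on [0.05, 0.5]
with per-population jitter (SD 0.05).

Haplotypes use copy-with-mutation: the first variant of a block is drawn
from its population frequency, each later variant copies the previous
column and flips alleles with probability m = (1 − √r²_target)/2.
Perfect taggers are exact haplotype copies under indel alleles, so their
realized r² is exactly 1; partial taggers use the same flip rule. This
construction is transparent and fast and exercises every pipeline stage;
it does not emulate coalescent genealogies, recombination hotspots,
allele-frequency spectra, or population divergence beyond frequency
jitter, so passing tests demonstrate correctness of the machinery, not
realism of human LD.

Twenty cis effects (β = 1.5, noise SD 1) are planted under all model
codings: eight shared across all six populations (the three REC and
three DOMDEV plantings sit here, plus two ADD), six population-specific
(three DOM, three ADD), six in exactly two populations (ADD). Planted
frequency is 0.3 for ADD/DOM and 0.5 for REC/DOMDEV: the REC indicator
is too rare at 0.3 (q ≈ 0.09) and the het term is near-collinear with
dosage away from 0.5 (cov(g, het) = q(1 − 2f)), so 0.5 gives those
codings the noncentrality the design intends. ADD — which detects with
probability ≈ 1 at these settings — carries the sharing patterns whose
labels a single under-powered population could flip. A quarter of the
planted effects sit on indels. One caveat: with ~90 (planting,
unplanted-population) null combinations per run, a planted-specific pair
occasionally also clears 10⁻⁴ in a second population by chance
(probability ≈ 2% per run), in which case the pipeline's sharing label
legitimately differs from the planted one.

A separate no-effect manifest (one population × 100 samples, 500
independent variants, 40 genes) measures null behaviour; its ~2,000
cis tests per scan × 51 permutations give the ≥ 10⁵ permuted tests used
for min-P calibration.

## Problem sizes and numerical choices

The default test suite and `scripts/acceptance.py` run the demo at
6 × 80 samples / 2,000 variants / 100 probes (seconds per full
six-population scan via the vectorized engine) and the null calibration
at ~10⁵ permuted tests — sizes chosen so every claim is recomputed from
scratch on a laptop-class machine. NA propagates as NaN internally and
prints as "NA" in TSV output; p-values below 10⁻⁴ print in scientific
notation. Seeds derived from a user seed stay below 2³¹.

## Interfaces and limitations

Gene models are read from BED12 (name = gene ID, thickStart/thickEnd
delimit the CDS, equal thick coordinates mean non-coding); this is the
single gene-model interface, exercised end-to-end by the generator's
own output. Regulatory features are generic user-supplied BED intervals;
no consequence prediction (TFBS, conservation, DNase) is performed.
Trans-eQTL analysis, genotype imputation, liftover, multiallelic
normalization and microarray preprocessing are out of scope. The CLI
validates thresholds and input paths (usage errors exit 2, domain errors
exit 1) and logs to stderr only.
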