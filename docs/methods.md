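# Methods

This note documents the statistical model behind each stage of the
screen, the defaults and why they were chosen, what the simulator does
and does not emulate, and the package's known limitations.

## Data model and conventions

All inputs are marginal association summary statistics: per variant an
effect estimate β (per effect-allele copy; log-OR for case-control
traits), its standard error, a p-value, optionally the effect-allele
frequency and sample size. Coordinates are 1-based inclusive; alleles
are assumed to be reported on the forward strand, with strand
resolution deferred to harmonization. A p-value inconsistent with
|β/se| under the two-sided normal (more than 0.5 in −log₁₀) is warned
about and recomputed from β/se, because every downstream formula uses
the z-statistic, not the file's p. Reported p-values are floored at
1e-300: the two-sided normal tail underflows double precision near
|z| ≈ 38.6, which well-powered loci legitimately exceed.

LD enters only as a correlation matrix r with a companion variant list
(the common plain-text LD-reference export); the package never computes
LD from genotypes. Matrices are required to be symmetric to 1e-8 (then
symmetrized), with unit diagonal to 1e-6.

## Instrument selection

cis windows come in two conventions, matching the two kinds of eQTL
sources the screen is designed around: `flank_gene` (window beyond
either end of the gene body; default 1,000 kb) and `midpoint` (window
around the gene midpoint; default 100 kb). Instruments are eQTLs inside
the window at p < 1×10⁻⁵, greedily clumped at r² < 0.1: repeatedly keep
the smallest-p remaining variant and remove everything correlated with
it at or above the threshold. Ties on p break by position and then
variant id, so results are identical across platforms. The greedy order
guarantees the output contains the globally most significant variant,
satisfies every pairwise r² constraint, and is idempotent; because a
stricter p-threshold truncates the same p-sorted candidate list, the
kept set shrinks as a subset when the threshold is lowered.

Variants absent from the LD reference are dropped with a warning by
default — treating unknown LD as zero would overstate independence. For
pre-pruned sources whose top SNPs may lack LD coverage, a
`missing_ld="independent"` flag keeps them; supplying no LD reference
skips clumping with a logged notice. No weak-instrument F-statistic
filter is applied.

## Harmonization

For each variant shared between exposure and outcome, the outcome
record is re-expressed on the exposure's effect allele: identical
labels pass through; swapped labels negate β and replace eaf by 1−eaf;
complementing the outcome's alleles resolves strand flips, after which
the identical/swapped logic applies. Palindromic variants (A/T, G/C)
are strand-ambiguous from labels alone. The default policy
(`infer_by_frequency`, ambiguity threshold 0.42) aligns them so the two
sides' allele frequencies fall on the same side of 0.5, negating β when
a flip is required, and drops them when either frequency is missing or
either minor-allele frequency exceeds the threshold; `drop_all` is
available for strictness. INDELs and anything not a single-nucleotide
A/C/G/T pair are dropped as mismatches. Every decision is recorded as
an action code per variant, retained in the output for audit.

The key correctness property, tested both at the unit level and end to
end, is flip invariance: re-expressing either input on the opposite
allele changes nothing about retained pairs, aligned effects, or the
downstream MR estimate.

## Mendelian randomization

With a single instrument the causal effect of exposure on outcome is
the Wald ratio β_out/β_exp; its default standard error is the
first-order delta approximation se_out/|β_exp| (the convention of
standard two-sample MR software), with the second-order form — adding
the exposure-noise term β²_out·se²_exp/β⁴_exp — available by flag. With
k > 1 instruments the IVW estimate is the precision-weighted
combination of per-variant ratios, equivalently the zero-intercept WLS
of β_out on β_exp with weights 1/se²_out. The default variance model is
multiplicative random effects: the fixed-effect SE (Σw)^(−1/2) is
inflated by max(1, φ̂), where φ̂ is the weighted residual SD about the
fit — the common default of the MR software this interface mirrors; the
floor at 1 means MRE never claims more precision than the fixed-effect
model, and k = 1 forces the fixed-effect form, which is then exactly the
first-order Wald ratio. p-values use the standard normal throughout
(summary-statistics convention, no t correction).

Families of tests are corrected by Benjamini–Hochberg:
q₍ᵢ₎ = minⱼ≥ᵢ p₍ⱼ₎·m/j, capped at 1. The default family is per outcome
across all gene × cell-type tests for that outcome; a `global` family is
available, since either reading of a multi-outcome screen is defensible.

Cross-cell-type agreement of MR results is summarized by the weighted
Pearson correlation of estimates over shared (gene, outcome) keys, with
default weights 1/(se²_x + se²_y) — the precision of the difference of
the two estimates; equal weights reduce it to the plain Pearson r.
Pleiotropy-robust estimators (MR-Egger, weighted median) are
deliberately out of scope: the screen's typical exposure has one or two
instruments, too few for them.

## Colocalization

Under the one-causal-variant-per-trait assumption, the evidence that
SNP j is causal for a trait is its approximate Bayes factor: with
z = β/se, V = se² and prior effect variance W,
log ABF = ½[log(1−r) + r·z²], r = W/(W+V) — the exact marginal
likelihood ratio of the normal-normal model, which the tests verify by
numerical quadrature. Prior effect SDs default to 0.15 (standardized
quantitative traits) and 0.2 (log-odds, case-control), the established
defaults of the colocalization literature; they are configurable
because the appropriate W depends on the trait scale.

The five hypotheses are scored by summing prior × BF over their
configurations: H1/H2 over the Q single-trait choices, H4 over the Q
shared choices, H3 over the Q(Q−1) distinct pairs, computed as
(Σ BF₁)(Σ BF₂) − Σ BF₁BF₂. All sums run in log space via log-sum-exp;
the H3 subtraction uses a stable log-diff-exp clamped at zero (the
difference is mathematically non-negative, and is exactly zero at
Q = 1). Posteriors are the softmax of the five log weights with per-SNP
priors p1 = p2 = 1×10⁻⁴, p12 = 1×10⁻⁵; a warning is emitted if
Q·(p1+p2+p12) approaches 1. Equivalence with brute-force enumeration
over all Q²+2Q+1 configurations is enforced to 1e-10 relative error in
the tests, as are exact normalization and trait-swap symmetry.

### Multiple signals

Loci can carry several independent associations, and a shared variant
for one signal pair can hide behind a larger unshared signal. The
package handles this with stepwise conditional decomposition:
conditional z-statistics z_j|S = (z_j − R_{j,S}R_{S,S}⁻¹z_S)/√(1 −
R_{j,S}R_{S,S}⁻¹R_{S,j}) (a 1e-6 ridge stabilizes R_{S,S}), forward
selection of index SNPs while the best conditional p < 1e-6 up to 10
signals, then one conditional statistics set per index (conditioned on
the others). Colocalization runs on every cross pair of the two traits'
signal sets and the maximum PPH4 is reported. This is a deliberate,
documented approximation of fine-mapping-based multi-signal
colocalization (sum-of-single-effects credible sets): it shares the
structure — one coloc per signal pair, max PPH4 — but not the
fine-mapping algorithm, and is not claimed to reproduce it numerically.
The conservative defaults (p_enter 1e-6, cap of 10 signals) keep the
signal count low; a null decomposition falls back to the marginal
statistics.

## Pipeline

The screen runs in three stages: (1) discovery MR over every
gene × cell-type × outcome with per-outcome BH at q < 0.05; (2)
replication MR restricted to stage-1 survivors after coarsening
discovery cell types to the replication source's labels (many-to-one,
deduplicated), with BH within the survivor family — consistent with
testing only discovery-significant targets; (3) colocalization of the
discovery exposure's full-region statistics (not just the instruments)
against the outcome, using the multi-signal mode when the exposure had
more than one instrument, with PPH4 ≥ 0.8 as the pass criterion. The
final flag is the conjunction of the three stage criteria, so the stage
pass sets form a monotone funnel by construction; per-stage tables and
the funnel counts are always written when an output directory is
configured. A bundled 14→6 cell-type map covers the common PBMC
fine-to-coarse reclassification (B lineage, CD4⁺ T, CD8⁺ T, NK,
monocytes, DC).

## Synthetic data

The simulator generates marginal statistics directly in z-space from
the standard multivariate-normal model: for standardized per-SNP causal
effects b and LD matrix R, the marginal z-vector is
MVN(√n·R·b, R). This is exact for every summary-statistics method under
test and avoids genotype simulation entirely. Dosage-scale values are
recovered via se_j = 1/√(2n·f_j(1−f_j)), β_j = z_j·se_j, with EAFs
f_j ~ Uniform(0.05, 0.5) drawn once per locus and shared by both traits
— the same variants in the same population; per-trait frequencies would
distort the true Wald ratio at a shared causal variant. Traits are on
the standardized scale (SD 1), so the quantitative-trait coloc prior
applies without rescaling; case-control outcomes use the effective-n
approximation se_j ≈ 1/√(2n·φ(1−φ)·f_j(1−f_j)) with case fraction φ,
documented as an approximation.

LD is block-diagonal AR(1) (r_ij = ρ^|i−j| within a block; default
ρ = 0.9, one block), positive semi-definite by construction. Causal
configurations follow the five colocalization hypotheses; under H4 with
mediation the outcome effect at the shared variant is α times the
exposure effect, making the true Wald ratio exactly α. Under H3 the
outcome's causal variant is the SNP with the largest r² to the
exposure's causal variant not exceeding the configured cap — one knob
covers both the near-independent calibration setting (cap 0.01) and the
maximally confounded pipeline setting (cap 0.5). Default study
conditions: α = 0.2, exposure causal variance 5% at n_exp = 10,000
(marginal |z| ≈ 22 at the causal SNP), outcome causal variance 1% at
n_out = 50,000, Q = 100 SNPs per locus; replication re-draws the noise
at its own sample size (default: the discovery n). Multi-gene studies
assign each gene a truth label (mediated in one designated cell type /
LD-confounded / null); cell types share each gene's locus and truth but
draw independent marginal noise. Every locus derives its generator
deterministically from (seed, gene, cell type, stage), so any subset is
reproducible in isolation.

What the simulator does **not** emulate — and what passing tests
therefore do not establish about real data: realistic MAF spectra and
LD from population haplotypes; sample overlap and shared donors across
cell types (real single-cell eQTL panels measure all cell types in the
same individuals, correlating their noise); pervasive polygenicity and
horizontal pleiotropy; winner's-curse selection in the eQTL source;
annotation-dependent architecture. The calibration results show the
estimators are correct under their own model, not that the model
captures every feature of cohort data.

## Validation studies and problem sizes

The self-validation studies (in `mrcoloc.validation`, exercised by the
test suite and by `scripts/acceptance.py`) use these sizes, chosen to
make Monte Carlo error small relative to the margins being checked:
200 random loci (Q ≤ 20) for enumeration-oracle equivalence; 500 loci
per scenario at Q = 500, n = 10,000, 1% causal variance for posterior
calibration; 1,000 mediated loci at α = 0.2, n = 50,000 for Wald/IVW
recovery and coverage (the IVW arm uses three causal signals in three
uncorrelated LD blocks, one instrument per block); 40 replicates of
10,000 null tests for FDR control; 200 random LD matrices and 1,000
variant pairs for the clumping/harmonization invariants; and the
60-gene end-to-end study (15 mediated / 15 confounded / 30 null).

## Known limitations

- The one-causal-variant assumption of the colocalization model is
  relaxed only through the stepwise-conditional approximation described
  above, not through full fine-mapping.
- First-order Wald SEs ignore exposure-side noise; this is accurate for
  the strong instruments the p < 1×10⁻⁵ filter admits, and the
  second-order form is available where instruments are weaker.
- No proxy-SNP lookup: instruments absent from the outcome are dropped.
- The effective-n case-control SE formula ignores covariate adjustment
  and case-control imbalance beyond the φ(1−φ) factor.
- Conditional z-statistics inherit any mismatch between the LD
  reference and the association panel; the ridge guards only against
  numerical singularity, not reference mismatch.
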