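# Methods

## Model and procedure

`rmescope` treats a clonal panel as a genes × clones array of allele-resolved
observations. The unit statistic is the allelic ratio
AR = 129/(CAST + 129) − 0.5, computed from allele-assigned read counts; an
abundance-based variant (per-allele TPMs) is available when the panel carries
per-allele abundance matrices, but counts are the default because the two
give equivalent calls at usable depth and counts are always present.

Classification is deliberately rule-based rather than model-fitted: the field
defines monoallelic expression by thresholds on AR and on the fraction of
clones affected, and the package reproduces that contract exactly so its
outputs are comparable with published gene lists. The decision cascade per
expressed gene is: annotation (X-linked, then Y-linked, then imprinted) →
ME-fraction test → both-alleles test. The both-alleles rule is what separates
*random* monoallelic expression from genetically fixed aME: a single clone on
the minority allele is sufficient, and no statistical test is layered on top
at classification time (skew testing is a separate, explicit step).

### Conventions and edge cases

- **Sign convention.** Positive AR = 129-biased, negative = CAST-biased,
  fixed throughout (including the simulator and the CAST TPM − 129 TPM
  difference, whose sign is the negative of the AR's).
- **Inclusive cutoffs.** AR ≥ +cutoff and AR ≤ −cutoff are monoallelic; the
  boundary value itself is a monoallelic call.
- **Undetermined clones** (fewer than `min_informative_reads` allele-assigned
  reads, default 10) are excluded from the ME-fraction denominator: a clone
  with no allelic information is evidence of nothing. The default floor is a
  pragmatic noise guard — a ratio from a handful of reads is dominated by
  sampling — and is configurable.
- **Expression filter.** Mean TPM across all clones strictly greater than 5;
  a gene at exactly the floor is excluded.
- **Per-gene overrides.** Genes whose AR distribution separates into three
  groups at other cutoffs (the Pvt1-style case) can carry a symmetric ±0.2
  override; overrides apply to clone states and are ignored during threshold
  sweeps, which explore global cutoffs.
- **Y_LINKED group.** Y-linked genes get their own group rather than being
  folded into X_LINKED or dropped, so the output partitions the gene list
  while still excluding all sex-linked genes from aME calling.
- **Variance estimator.** AR mean/variance summaries use the sample (n−1)
  variance; with a single determined clone the variance is NaN, never 0.
- **Percentage style.** Group shares of expressed genes are reported both
  truncated to one decimal (the convention used for printed gene-list
  fractions, e.g. 2.781 → 2.7) and at full precision.

### Downstream statistics

- **Fold bias** = majority/minority monoallelic clone counts; infinite when
  the minority is zero (reported as `inf`, never clipped).
- **Balance test**: two-sided *exact* binomial test against p = 0.5. Panels
  have at most a few hundred clones, so exactness is free; no normal
  approximation is used.
- **Compensation and AR-shift tests**: Welch (unequal-variance) two-sample
  t, two-sided. Group means are reported with their sign so both
  over-compensation (mono > bi) and dosage-loss patterns are representable.
- **Cis-coupling**: Pearson r and r² with pairwise deletion of undetermined
  clones; at least 3 determined pairs required; zero variance in either
  vector yields NaN rather than a spurious coefficient.
- **Stability drift**: max |AR_t − AR_0| plus the least-squares slope of AR
  on passage number.
- No multiple-testing correction is applied inside these functions; a
  panel-wide FDR, if wanted, belongs to the caller.

## Motif comparison

The allele comparison needs only a best-hit log-odds score per allele, so the
scanner is a direct PWM log₂-odds scan: probabilities get a per-cell
pseudocount (default 0.01, renormalized), the background defaults to uniform
0.25, both strands are scanned, windows containing N are skipped, and ties
break to the smallest start with forward strand first. No p-value/E-value
calibration is performed — the scientific use is a signed stronger/weaker
comparison between two alleles (delta = best_129 − best_cast), which is
antisymmetric under allele swap by construction. JASPAR bracket files and
bare four-row A/C/G/T matrices are both accepted (parsed via biopython).

## qPCR contract

The ΔΔCt arithmetic is stated fully because prose descriptions of
fold-over-input are notoriously ambiguous:

```
corrected_input = ct_target_input − log2(1/input_fraction)
log2_fold = (corrected_input − ct_norm_input) − (ct_target_sample − ct_norm_sample)
fold = 2^log2_fold
```

The normalizer is applied symmetrically to sample and input. This choice
reproduces the 4.32-cycle correction for a 5% input, is invariant to a
constant plate offset on all four Ct values, and gives fold = 1 when the
sample equals the corrected input. Amplification efficiency is implicitly 2
(the log2 convention); no efficiency modeling is attempted.

## Synthetic panel generator

The simulator encodes the generative picture the analysis is designed to
detect, with ground truth for every gene and clone:

1. **Commitment.** Each aRME-class gene in each clone becomes monoallelic
   with probability `f_me` (default 0.6), else stays bi-allelic.
2. **Choice.** If monoallelic, the expressed allele is drawn: 0.5/0.5 for
   balanced aRME; fixed for one-allele aME; for skewed aRME,
   P(ME allele = CAST) = logistic(κ·(a₁₂₉ − a_CAST)/(1 + tf_level)). The
   logistic form is the simplest monotone, symmetric, saturating map with
   the three qualitative properties the two-step mechanism requires: balance
   at equal affinities, the *higher*-affinity allele ending up silenced
   (activated first, then shut down), and loss of skew as the factor's
   level rises. Defaults (a₁₂₉ = 2, a_CAST = 1, κ = 2.639, tf_level = 0)
   put the choice probability at 56/60 ≈ 0.933 — the canonical strongly
   skewed case, a ~14-fold expected clone-count bias.
3. **True allelic fraction.** Monoallelic clones sit at leakage/1 − leakage
   (default 0.02) rather than exactly 0/1, since real "monoallelic" clones
   retain trace minority-allele signal; bi-allelic clones sit at 0.5.
4. **Observation.** Total reads ~ negative binomial with mean
   `mean_expression × reads_per_tpm` (× `compensation`, default 1.5, in ME
   clones of aRME/aME genes) and variance m + dispersion·m². Informative
   reads are a binomial thinning at `snp_informative_fraction`; the default
   0.632 = 1 − e⁻¹ is the Poisson probability that a ~100 b read overlaps at
   least one SNP at ~1 SNP/100 bp density. The 129-allele read count is
   beta-binomial around the true fraction with intra-clone correlation
   `rho` (default 0.05): bulk sequencing averages bursting out, but residual
   overdispersion remains and `rho` exposes it.
5. **Context genes.** Imprinted-like genes use one fixed parental allele in
   every clone; X-like genes are monoallelic in every clone — a random
   allele per female clone (X-inactivation), the maternal (129) allele in
   male clones. Both classes are emitted with matching annotation lists, so
   the classifier's annotation precedence is exercised end to end.
6. **Neighbor coupling.** Each skewed gene emits a neighbor whose true AR is
   −coupling_strength × focal AR plus Gaussian noise (sd 0.05), clipped to
   the valid range — the enhancer-competition signature, recoverable by the
   coupling statistic.

Panel defaults (120 clones, 74 female / 46 male; ~1000 reads per gene-clone,
~630 informative) match a realistic clonal-panel study; all draws flow from
one seeded generator, so a fixed seed reproduces the panel byte for byte.

**What the simulator does not emulate:** genome positions and linkage, read
sequences, mapping or SNP-assignment bias toward the reference allele,
library-size variation between clones, correlated ME across genes, and clone
lineage structure. Passing recovery tests therefore show that the
classifier's logic and thresholds behave correctly under the stated noise
model — not that real panels are free of mapping or annotation artifacts.

## Problem sizes and tolerances in the test suite

Recovery checks run on a 200-gene × 100-clone panel (~630 informative reads
per cell, rho = 0.05, f_me = 0.6), a scale at which class recovery is
expected ≥ 95%: the residual errors are genuine sampling events, mostly a
one-allele aME gene picking up a single noise clone past the opposite cutoff
and being promoted to ARME. Replicate-based checks use 500 single-gene
panels (balance test, null true, α = 0.01) and 200 single-gene panels
(skew, median fold within [7, 28]). The exact binomial test is verified
against full enumeration for every (k, n) with n ≤ 200; the motif scanner
against exhaustive window enumeration on sequences up to 50 bases. Floating
comparisons use relative tolerances of 1e−6 to 1e−9; the classifier itself
is exact arithmetic on counts.

## Known limitations

- Classification is threshold-based by design; genes near a cutoff flip
  groups under small count perturbations. The threshold sweep is the
  intended sensitivity analysis.
- X-inactivation state is never inferred; X/Y/imprinted handling is purely
  annotation-driven, so unannotated sex-linked genes in a single-sex panel
  will surface as aME candidates.
- The balance and compensation tests are per-gene; panel-wide screening
  across thousands of genes needs an external multiplicity correction.
- Abundance-mode AR requires per-allele abundance matrices, which many
  upstream quantifications do not emit; counts mode is the canonical path.
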