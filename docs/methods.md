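# Methods

This note records the models, estimators and conventions implemented in
`condiv`, the choices made where several defensible options exist, and
what the synthetic-data generator does and does not emulate.

## Data model and quality control

A `GenotypePanel` stores diploid biallelic calls coded 0/1/2 against an
arbitrary per-variant reference allele, with −1 for missing; every
statistic in the package is symmetric under swapping the two alleles, so
the coding orientation only matters for file round trips (`reader_oriented`
normalises a panel to the convention the PED reader produces). Breed
labels ride on the samples; FAO class and origin are optional metadata.

Quality control mirrors routine chip filtering, in a fixed order so the
per-filter counts are unambiguous: (1) drop non-autosomal variants
(default autosome labels "1"–"28", the chicken autosomes; configurable),
(2) drop variants with a missing-call rate ≥ 10%, (3) drop variants with
pooled minor-allele frequency ≤ 5%. Both boundaries are strict — a
variant exactly at a threshold is removed — and MAF is computed on all
breeds pooled, since filtering precedes any per-breed analysis. Each
removed variant is counted once, at the first rule it fails.

## Within-breed diversity

Allele frequencies use called genotypes only: p = (2n_bb + n_ab)/(2n).
Ho is the mean called-heterozygote fraction across loci; He the mean
2p(1−p), with an optional 2n/(2n−1) small-sample factor; MAF the mean
folded frequency.

**FHOM** is the method-of-moments inbreeding coefficient
(O_hom − E_hom)/(L − E_hom) per individual, averaged per breed, with
E_hom the Hardy–Weinberg homozygote expectation at reference frequencies
including the 2n/(2n−1) correction. Reference frequencies default to the
pooled panel (the single-run convention of chip-QC tooling); a
within-breed option exists and is the right choice when breeds are
strongly differentiated, because pooled references fold the Wahlund
effect into the estimate. Parameter-recovery tests use the within-breed
option for exactly that reason.

**Coancestry indices.** The molecular coancestry of two individuals at a
locus is the mean of the four allele-identity indicators; the raw
self-coancestry of an individual is s = 1 − h/2. Averaged over distinct
pairs and loci, the pairwise mean satisfies the closed form
f_obs = [n(1−He) − 1 + Ho/2]/(n−1), which the implementation uses
(a brute-force indicator count backs it in the tests). Both indices are
reported as deviations from the within-breed Hardy–Weinberg expectation,
scaled by the maximum possible deviation, and **signed so that positive
means homozygote excess**: fii = (f_exp − f_obs)/(1 − f_exp) and
si = (s_obs − s_exp)/(1 − s_exp). The sign convention deserves a note:
an excess of heterozygotes *raises* pairwise allele sharing above the
random-mating expectation (algebraically, f_obs − f_exp =
(Ho − He)/(2(n−1))), so the deficit orientation is the one under which
fii < 0 flags heterozygote excess — the interpretation used in
conservation summaries of these indices, and the sign pattern the package
asserts on every simulated panel. The absolute scaling applied by
gene-bank software to these indices is not standardised; only signs and
orderings should be compared across implementations.

## Between-breed differentiation

Nei's minimum distance is computed over the loci where both breeds have
calls, clipped at zero against floating-point underflow. Weir–Cockerham
θ uses the standard locus-wise variance components (a, b, c) with
observed sample sizes and heterozygosities, combined as a ratio of sums
over loci; loci enter only if every breed has ≥ 2 called genotypes. θ can
dip slightly below zero at small n — that is the estimator's sampling
correction, not a bug. The companion `simple_fst` is the textbook ratio
σ²_p/(p̄(1−p̄)) with the *population* variance across the r observed
breeds (so two breeds at p = 0.2 and 0.8 give exactly 0.09/0.25 = 0.36);
under this convention it approaches θ·(r−1)/r, not θ, as sample sizes
grow — the Bessel factor separates "variance of these breeds" from
"variance of the drift process", and the tests compare the two
accordingly.

Neighbor joining is the standard Saitou–Nei algorithm with two
determinism guarantees: Q-criterion ties break on the smallest pair of
original taxon indices, and a negative branch length is clamped to zero
with the deficit transferred to the sibling branch so the joined-pair
distance is preserved. On exactly additive matrices the generating
topology and branch lengths are recovered to floating precision
(cross-checked against scikit-bio's implementation); on non-additive
matrices, different clamping policies across packages legitimately yield
slightly different negative-branch handling.

## Diversity partitions and contributions

Both partitions treat breeds as units (unweighted means over breeds,
regardless of sample size, matching collections of near-equal cohorts);
loci where any included breed has zero called copies are skipped for the
whole partition. H_S is the mean within-breed 2p(1−p), H_T the value at
the unweighted mean frequency, D_G their difference — which equals the
mean of all n² pairwise Nei minimum distances, an identity the test
suite verifies to 1e−12. Allelic richness k_i counts distinct alleles
per breed per locus, either raw or rarefied to g = the smallest called
gene-copy count across breeds at that locus, using the hypergeometric
presence expectation 1 − C(N−c, g)/C(N, g); shared richness k_ij uses
the product of presence probabilities (independent subsamples). Raw mode
is retained because the count-based formulas are the definitional ones;
rarefaction is the default because it removes sample-size bias when
cohorts are unequal.

Leave-one-out contributions divide every component difference by the
*total* (H_T or A_T) of the full collection, and report c_total as the
sum c_within + c_between, making each row additive to machine exactness.
All leave-one-out runs reuse the full-panel locus mask so that a
contribution reflects breed removal only, never a change of locus set.
A monomorphic locus contributes zero to every component and is retained;
it dilutes all runs identically. Note that a breed exactly duplicating
another is *near*, not exactly, zero on the divergence column: removing
it shifts the unweighted mean frequency.

## LD and effective population size

r² is the squared Pearson correlation of genotype dosages (composite LD;
no phasing needed) over individuals called at both loci, restricted to
within-breed-polymorphic loci on the same chromosome within a distance
cap, with pairs under 5 complete observations skipped and optional
seeded subsampling per chromosome to bound runtime. Binned means are
inverted through the drift expectation E[r²] ≈ 1/(1 + 4N_e c), with
c from the bin midpoint under a constant map (default 1 cM/Mb) and each
bin mapped to t = 1/(2c) generations. The map rate is the dominant
source of absolute N_e scale uncertainty (chicken macro- and
micro-chromosomes differ several-fold); comparisons between breeds on
the same map are unaffected. The 1/(2n) sampling correction is optional
because the conventions of LD-N_e tools differ; the inversion is exact
on synthetic Sved curves when it is off.

## The synthetic generator

Breed frequencies drift from a shared ancestral frequency (default
Uniform(0.05, 0.95)) under the Balding–Nichols Beta model, whose
parameter F *is* the breed's target Fst — estimates are therefore
compared to the drift parameter, not to a realised-matrix Fst.
Genotypes are drawn with a per-breed inbreeding coefficient; missing
calls are masked i.i.d.; all randomness flows from one seed through
per-breed substreams, so identical configurations are bit-identical.
Defaults mirror a realistic gene-bank panel: 16 breeds × 20 samples,
tens of thousands of SNPs spread over 28 autosomes, Fst ≈ 0.15, 1%
missingness.

Loci are unlinked by default. The optional block mode arranges loci in
blocks whose members are Markov copies of their neighbour, with per-step
retention √(1/(1 + 4N_e c_step)) for a per-breed target N_e — planting a
breed-specific, monotone LD decay for the estimators to detect. This
yields an exponential, not exactly hyperbolic, decay profile, so LD
tests assert orderings and round trips rather than absolute N_e values.
The generator does not emulate mutation, selection, migration,
pedigree structure, genotyping batch effects, or realistic chromosome-
scale recombination maps; passing tests demonstrate estimator
correctness under the stated model, not robustness to those factors.

## Problem sizes and numerical choices

The test suite runs desk-scale: partition identities on 100 random small
panels (≤ 7 breeds, ≤ 40 SNPs), parameter recovery on 4 breeds × 50
samples × 2000 SNPs (θ within ±0.02, FHOM within ±0.05), NJ on 50 random
additive matrices of 4–8 taxa (1e−9), and the LD contrast on two breeds
× 3000 SNPs in block mode. The acceptance script simulates the full
16-breed census (315 birds) on 6000 pre-QC SNPs including a Z chromosome,
with per-breed inbreeding set to the published FHOM column and a uniform
drift level of 0.20 (per-breed differentiation is not published).
Degenerate inputs are reported as NaN (FHOM with a degenerate reference,
fii for single-sample breeds, indices when all loci are monomorphic)
rather than raised, except where a computation is impossible (no shared
loci, all variants filtered, fewer than 3 NJ taxa / 3 leave-one-out
breeds), which raises with an actionable message.

## Known limitations

Binary PLINK (BED) is not parsed; genotypes are treated as unphased;
the absolute scaling of fii/si is package-specific (signs and orderings
are the comparable quantities); N_e estimates inherit the constant-map
assumption; and the priority score is a deliberate simplification — a
rank sum with optional weights — not a multi-criteria decision analysis.
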