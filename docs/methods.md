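# Methods

This note documents the statistical machinery, the generative model behind
the synthetic populations, the numerical choices, and what the test suite
does and does not establish.

## Relatedness estimation

The core statistic is the symmetric Lynch–Ritland pairwise relatedness
estimator r_LR. It is a method-of-moments estimator of the relatedness
coefficient (the expected proportion of alleles identical by descent
relative to a reference population): 0 for unrelated fish, 0.25 for
half-sibs, 0.5 for parent–offspring or full sibs. Each locus yields a
directional estimate and a weight (formulas in the `relatedness` module
docstring); the multilocus directional estimate is the weight-averaged sum
over loci defined in that direction, and the symmetric estimate averages
the two directions. Design points:

- **Undefined loci.** A locus is undefined for a direction when the
  denominator vanishes (this happens, e.g., for a heterozygous reference
  whose two alleles have frequencies summing to 1 with product 1/4, and
  always for monomorphic loci). Undefined loci are *absent* from the sum,
  never zero-filled; when only one direction is defined at a locus the
  defined direction alone contributes, and the symmetrization averages the
  two directional multilocus values over their own defined loci.
- **No truncation.** Negative estimates are informative (they indicate
  fewer shared alleles than random draws from the reference population
  would give) and are retained everywhere.
- **Retention filter.** A dyad enters the analysis only when both fish
  were successfully genotyped at ≥ 10 of the 20 loci; the filter is
  per-individual, matching how multilocus estimates lose stability with
  missing loci.
- **Reference frequencies.** Allele frequencies are estimated from a
  kinship-thinned subset — the dominant male plus at most one uniformly
  chosen adult female per territory — so large families do not distort the
  frequency spectrum. Alleles observed in a dyad but absent from the
  reference subset are added at frequency 1/(2·n_ref + 1) with
  renormalisation (dropping such loci would bias exactly the pairs that
  carry rare alleles); each augmentation is logged.
- The estimator is unbiased: over 2,000 simulated dyads per pedigree class
  on study-like loci the class means land within ±0.01 of 0, 0.25 and 0.5
  (the acceptance suite asserts ±0.02).

## Marker polymorphism and Hardy–Weinberg testing

Expected heterozygosity is the plain 1 − Σp² (no small-sample correction).
The HWE test is a chi-square on genotype counts with two pooling steps:
alleles with fewer than 5 observed copies are pooled into one allele class,
and genotype classes with expected count < 1 are merged into a single
class; degrees of freedom are (number of genotype classes) − (number of
allele classes), floored at 1. Under simulated Hardy–Weinberg genotypes
this rejects at ≈ 0.3% for α = 0.0025 and ≈ 5% at α = 0.05. A seeded
Monte-Carlo exact variant (alleles shuffled into genotypes, same statistic)
is available as `hwe_test(..., method="exact-mc")`. The Bonferroni pass
threshold defaults to α = 0.0025 (20 loci).

## Within-group mixed model

`PairingMixedModel` fits a Gaussian LMM of within-group r_LR on the dyad
category (FF/MM/FM/JJ) with a random intercept per social group, by REML
(statsmodels MixedLM). Individual fish identities are deliberately not
modelled: a dyadic design cannot separate intra- from inter-individual
variance here, and each within-group dyad belongs to exactly one group.
All six pairwise category contrasts are reported with single-step
(Tukey-style) adjustment: the adjusted p for contrast *i* is
P(max_j |Z_j| ≥ |z_i|) under the joint normal of the six contrast
z-statistics, evaluated by seeded Monte Carlo with 10⁵ draws. Contrasts
involving a category with fewer than 2 observations are reported as
undefined. If the estimated group variance collapses below 1e-8 the fixed
effects are re-solved by OLS — the exact zero-variance limit — which makes
the degeneracy property (`LMM → OLS within 1e-6`) hold identically. The
implementation is cross-checked in the test suite against R's
lme4 + multcomp on a common fixture (estimates to 1e-3, adjusted p to
0.02).

## Distance-decay GAM

`DistanceDecayGAM` models between-group same-sex adult relatedness against
inter-territory distance. The response is Yeo-Johnson transformed (the
transform handles the negative estimates; λ is fitted by Gaussian MLE,
bounded to [−2, 2] because more extreme λ produce numerically unstable
back-transforms for negligible likelihood gain; λ is fitted once on the
pooled response so both sexes share a scale). Each category gets a
penalized cubic B-spline smooth with five basis functions (knots at
distance quantiles), fitted with statsmodels GLMGam; the penalty weight is
chosen by generalized cross-validation over a log-spaced grid with ties
broken toward the heavier penalty, so a constant response collapses to a
smooth with one effective degree of freedom and a flat curve. Reported
per category: smooth edf (sum of spline-column edfs), an approximate F test
against the intercept-only model, and the fitted curve on a distance grid,
back-transformed to the r_LR scale. A sex-difference F compares
category-specific smooths against a shared smooth with a category offset.
edf values are smoothing-implementation-sensitive; the package asserts
curve *shapes* (decline amplitudes), not edf equality with any other
implementation, though the suite confirms agreement of fitted curves with
R mgcv (cubic regression splines, k = 5, GCV) to 0.02 on a common fixture.

## Density permutation tests

For each radius (50/100/150/200 cm, inclusive boundary) and category, the
observed statistic is the OLS slope of per-group mean within-group same-sex
r_LR (over multi-female / multi-male groups only) on the neighbour count.
The null distribution permutes the response without replacement 10,000
times; because the slope is linear in the response, all permuted slopes
are computed as one matrix product. The one-sided p is the proportion of
null slopes *strictly* more negative than the observed slope (with an
FP-tie guard so a constant response yields p = 0, not an artefact of
round-off); the add-one corrected (count+1)/(n_perm+1) is reported
alongside and is the better-behaved quantity when p is near 0. Each
(category, radius) cell draws from its own seed stream derived from the
master seed, so cells are independently reproducible.

## Synthetic populations

The generator emulates the study system — a fully sampled ~10 × 10 m
shell-bed quadrat of 128 territories — with enough demographic structure
to carry the standing kin patterns the estimators must detect.

**Territory map.** A clustered hard-core point process: proposal points
come from a 3-clump Gaussian intensity (sd 130 cm) over a 15% uniform
floor, and are rejected within 30 cm of an accepted territory. Surveyed
shell beds are strongly clumped; a homogeneous map would compress the
neighbour-count range that the density tests regress on. Setting
`cluster_weight = 0` recovers a homogeneous hard-core process.

**Demography.** Each territory holds one dominant male, up to
`male_queue_cap = 3` queueing subordinate males, and adult females
(founders ~ Poisson(1.9)). The population runs 14 overlapping breeding
cycles; per cycle:

1. adults die (females survive 0.85/cycle, males 0.74); a dead dominant is
   succeeded by his longest-queueing subordinate, or — if the queue is
   empty — by a subordinate taking over from a nearby group
   (exp(−d/60 cm) weighting), or failing that by an unrelated immigrant;
2. resident females may switch groups between broods (breeding dispersal,
   0.45 × p_f per cycle);
3. the previous cycle's offspring recruit (maturation 0.104 for females,
   0.15 for males — males enter queues at a higher rate, which is what
   balances male numbers given that male mortality must also be covered by
   recruitment) and natal dispersal is attempted with probability p_f = 0.9
   (females) or p_m = 0.2 (males);
4. every female spawns with the dominant male (Poisson(3.2) offspring),
   except that daughters skip spawning with their own father.

The census samples all living adults plus the final cohort's surviving
juveniles (0.52 to census). Genotyping failure is a mixture: 5% of fish
fail at 85% of loci (degraded samples), the rest drop 1.5% of loci — which
reproduces the ~95% pass rate of the ≥ 10-loci filter.

**Dispersal mechanics.** A mover draws a distance budget from its
sex-specific exponential kernel (d_f = 150 cm, d_m = 60 cm); territories
within budget are visited in kernel-weighted order and each admits the
joiner with probability 0.15 (residents resist prospective joiners).
Emigration success therefore rises smoothly with local territory
availability, and fish in sparse neighbourhoods stay home — the ecological
constraint on dispersal that the density permutation tests detect. With
p_f = p_m = 0 every fish remains in its natal group.

**What the defaults reproduce** (measured over replicate simulations):
mean group size ≈ 6.3–6.7 with 1.9–2.1 females, 1.5–1.65 males and 2.9–3.2
juveniles per territory; ~16 observable alleles per locus with expected
heterozygosity ≈ 0.75 (Dirichlet(0.28) frequency prior with a 0.008
rare-allele floor so nominal allele counts are observable at reference
sample sizes); ~95% retention; within-group male–male mean r_LR ≈ 0.3 vs
female–female ≈ 0.05–0.08; a steep short-range decline of between-group
male–male relatedness (fitted drop ≈ 0.02 over 0–200 cm) against a shallow
female–female decline (≈ 0.012); and a female-specific negative association
between within-group relatedness and neighbourhood density.

**What the generator does not emulate.** No mutation, linkage, selection,
null alleles or allele-calling error; no extra-group paternity; no
territory creation or extinction; founder immigrants are drawn from the
same panmictic frequency pool (no regional structure beyond the quadrat).
Passing tests therefore validate the *pipeline* — that each stage recovers
the structure a known pedigree implies — not any claim about parameter
values in real populations. The sex-specific emigration probabilities and
kernels are illustrative settings that reproduce the documented asymmetry,
not field estimates.

**A known calibration limit.** The relative power property "female density
p-value below the male one at the 100 cm radius" holds in ≈ 86–93% of
replicates (pooled ≈ 88%) under the frozen defaults. With 65 multi-female
groups and per-group mean noise of ~0.1–0.15 (kin-assignment lottery plus
estimator noise), the attainable slope z-statistic is bounded, so a
≥ 90%-of-replicates check sits at the boundary and can land a few
replicates short on a given seed. The corresponding acceptance test
asserts the 90% level regardless.

## Problem sizes

Simulated acceptance analyses use the full study shape (128 territories,
~820 fish, ~300k dyads); replicate-heavy checks (power and calibration
properties) use 20–50 replicates with within-group-only or
between-group-only relatedness sweeps, which compute in a few hundred
milliseconds each. The complete test suite runs in about two minutes; the
acceptance script in well under one.
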