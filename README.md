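# shellkin

Genetic inference of sex-biased dispersal in group-living, shell-dwelling
cichlids (*Neolamprologus multifasciatus*-type social systems), from
codominant microsatellite genotypes and territory coordinates.

Field biologists studying social fish often want to know which sex leaves
home: if females disperse and males queue on their natal territory, then
cohabiting males should be kin while cohabiting females are not, male
relatedness between *nearby* groups should exceed that between distant
groups, and female philopatry should be forced wherever there are few
neighbouring territories to move to. `shellkin` implements that whole chain
of inference as a tested pipeline, plus a pedigree-based population
simulator so every stage can be validated against known truth.

## What it computes

**Pairwise relatedness.** The symmetric Lynch–Ritland estimator r_LR. For a
reference genotype *(a, b)*, proband *(c, d)* and reference-population
allele frequencies *p*:

```
r = [p_a(δ_bc + δ_bd) + p_b(δ_ac + δ_ad) − 4 p_a p_b] / [(1 + δ_ab)(p_a + p_b) − 4 p_a p_b]
w = [(1 + δ_ab)(p_a + p_b) − 4 p_a p_b] / (2 p_a p_b)
```

Per direction, loci are combined weighted by *w*; the symmetric estimate
averages the two directions. Dyads are retained when both fish are
genotyped at ≥ 10 loci. Allele frequencies come from a kinship-thinned
reference subset (dominant male + one random adult female per territory),
and a marker-polymorphism summary (k, N, H_obs, H_exp, Hardy–Weinberg
test with Bonferroni α = 0.0025) documents the panel.

**Group structure.** Within-group dyads by category (female–female,
male–male, female–male, juvenile–juvenile), between-group same-sex adult
dyads with inter-territory distances, per-group mean same-sex relatedness
over multi-female / multi-male groups, and neighbourhood density (other
territories within 50/100/150/200 cm).

**Models.** A Gaussian mixed model of within-group r_LR on dyad category
with a random group intercept and all six Tukey-adjusted pairwise
contrasts (`PairingMixedModel(...).fit()`); a penalized cubic-spline GAM
(five knots, GCV) of Yeo-Johnson-transformed r_LR on distance per sex
(`DistanceDecayGAM(...).fit()`); and one-sided permutation tests (10,000
shuffles) of mean within-group same-sex relatedness against neighbour
counts at each radius (`DensityPermutationTest(...).fit()`).

**Simulation.** `simulate_population()` generates study-shaped populations
— a clustered shell-bed map, social groups with a dominant male, queueing
subordinates and plural-breeding females, overlapping breeding cycles,
sex-specific travel-budget dispersal, Mendelian genotypes, realistic
genotyping failure — with the full pedigree returned as ground truth.

## Worked example

```python
import shellkin as sk

table, tmap, truth = sk.simulate_population(sk.SimulationConfig(), seed=1)
freqs = sk.allele_frequencies(sk.reference_subset(table, seed=1), table)
pairs = sk.pairwise_matrix(table, freqs, territory_map=tmap)

win = sk.within_group_pairs(pairs)
for cat in ("FF", "MM"):
    print(cat, round(win[win.category == cat].r_lr.mean(), 3))

res = sk.PairingMixedModel(win).fit(seed=1)
c = res.contrast("MM vs FF")
print(f"MM vs FF: {c.estimate:.3f} +/- {c.se:.3f}, z = {c.z:.1f}")
```

prints (seed 1):

```
FF 0.054
MM 0.351
MM vs FF: 0.285 +/- 0.026, z = 11.0
```

Cohabiting females are nearly unrelated (mean r_LR ≈ 0.05) while
cohabiting males are close kin (≈ 0.35, between half- and full-sib
expectation); the mixed-model contrast puts the male–female asymmetry at
≈ 0.29 with overwhelming evidence — the genetic signature of female-biased
dispersal. The same objects expose the decay curves
(`DistanceDecayGAM(...).fit().curve_table()`) and the permutation grid.

The command line mirrors the library:

```bash
shellkin simulate --seed 7 --out sim/
shellkin analyze --genotypes sim/genotypes.csv --coords sim/coords.csv \
    --radii 50,100,150,200 --min-loci 10 --n-perm 10000 --seed 7 --out run1/
```

`analyze` also accepts a precomputed pairwise table
(`--relatedness pairs.csv`) in place of raw genotypes, so published
relatedness tables can feed the model stages directly.

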