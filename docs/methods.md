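# Methods

## The test

OVPDT is a region-level family-based association statistic for sequencing
data that treats common and rare variants with different selection
machinery and combines them on an equal footing.

**Per-variant statistic.** For nuclear family *i*, each triad (two
genotyped parents, one affected child) contributes
T = (minor alleles transmitted) − (minor alleles not transmitted); for
complete dosages this is T = 2·g_child − g_father − g_mother, which is
phase-free (the only ambiguous configuration, both parents and child
heterozygous, gives T = 0 under every phase). Each affected × unaffected
sib pair contributes S = g_aff − g_unaff. The family score D_i averages T
and S over the family's informative units (triads with ≥1 heterozygous
parent; cross pairs of sibships in which at least one pair differs). The
single-variant statistic is X = (Σ_i D_i)² / Σ_i D_i², chi-square with
1 df under the null of no linkage or association, and symmetric in
risk/protective labeling of the minor allele.

**Common variants (MAF > 0.05): ordered subset.** A genotype-relative-risk
score is computed per common variant from parental mating types only (see
below), variants are ranked by |lr|, and prefix sums of their X values are
scanned; prefix *i* gets the tail probability P(χ²_i ≥ S_i) as if the
variants were independent. C is the prefix sum at the minimum p-value if
that minimum is ≤ 0.05, else 0. Independence is of course violated under
LD; validity is restored by the permutation (below), which preserves LD,
so the scan is a selection heuristic, not an inferential step.

**Rare variants: variable threshold.** R_t = Σ X_i over {MAF < t} for
t ∈ {0.05, 0.03, 0.01, 0.005}. M_t = R_t + C (equal weights). Because the
four M_t have different null scales, each is standardised by the mean/SD
of its own permutation replicates, and M = max_t of the standardised
values; permuted replicates get the same treatment (same means/SDs) so M
is compared like with like. We standardise R_t + C jointly (not R_t
alone), following the description of the combined standardised statistic.

**Permutation.** Swapping a family's transmitted and non-transmitted
alleles negates all its T and S values, i.e. D_i → −D_i. One ±1 sign is
drawn per family per chromosome and applied to every variant of that
chromosome simultaneously, so both LD among variants and IBD sharing
among siblings survive. Only the numerators Σ_i s_i D_i change, so a
permutation batch is a single sign-matrix × D-matrix product. lr is a
function of parental genotypes only and is exactly invariant, so the
ordering is fixed once. p = (#{M_perm > M} + 1)/(K + 1).

**Adaptive stopping.** Permutations run in batches (first 2000, then
1000). After each batch the standardisation means/SDs and the exceedance
count are recomputed over *all* permutations so far (full-history
restandardisation avoids bias from stopping on a drifting null estimate).
Stop when exceedances ≥ 36 and K ≥ 2000, or at max_K. With the target at
36 the p-value's relative standard error at p ≈ 0.018 is ≈ 1/6.

## GRR estimation from parental mating types

Under HWE and ascertainment on ≥1 affected child, the conditional
probability of an unordered parental mating type (i, j) factorises into
an allele-frequency part and a part depending only on the genotype
relative risks r1 = f1/f0, r2 = f2/f0. Four ratios of mating-type
probabilities cancel the frequency part exactly (forms in
`ovpdt/grr.py`); their empirical counterparts are plug-in cell-proportion
ratios, estimable only when every involved cell is observed. r1 is fitted
by grid search over (0.5, 20) in multiplicative steps of exp(0.005) under
the additive penetrance constraint f1 = (f0 + f2)/2, i.e. r2 = 2r1 − 1,
minimising Σ |ρ_theoretical − ρ_observed| over the estimable ratios
(smallest r1 wins ties). The variance of log r1 comes from a multinomial
bootstrap over the six cells (B = 1000 by default; the simulation harness
uses a reduced B = 200, since the ranking score is insensitive to ~10%
Monte-Carlo error in the variance). lr = log r1 / √var; lr = 0 when no
ratio is estimable, when fewer than 10 bootstrap refits succeed, or when
the variance is 0.

Two structural facts worth knowing:

- Under the additive constraint, ρ1 ≡ 2 (uninformative) and ρ2 is
  symmetric in r1 ↔ 1/r1, so risk and protective fits of similar
  magnitude are near-twins separated only by ρ3/ρ4, which involve the
  rarest cells. Bootstrap refit distributions are therefore
  risk/protective mixtures, and var(log r1) shrinks slower than 1/n.
  This is a property of the estimator, and is why |lr| (not lr) is used
  for ranking.
- For rare variants the hom-minor parental cells are essentially never
  observed, so lr = 0 and the ordered-subset machinery is, by
  construction, a common-variant device.

## Numerical conventions

- MAF from parental genotypes only; variants with parental MAF = 0
  excluded; MAF exactly 0.05 is in neither the common set (> 0.05) nor
  the rare sets (< t), matching the strict inequalities.
- Missing genotypes: a unit (triad or pair) with any missing member at a
  site contributes nothing at that site; MAF uses the parents present.
- Mendelian inconsistency at a site zeroes that family's whole site.
- Degenerate denominators: X = 0 when all D_i = 0; a threshold whose
  permutation SD is 0 standardises to 0 on both sides; a region with no
  informative family is reported untestable with p = 1.
- Ordering ties: |lr| descending, then larger X, then position; lr = 0
  block last with the same internal tie-break. This makes the region
  p-value invariant to input variant order.
- RNG: per-region and per-variant counter-based seeding
  (SeedSequence(user_seed, spawn_key=(crc32(region), stream))), so
  results are reproducible under any execution order.

## The simulator

The generator emulates the study design the test was evaluated under:

- **Haplotype pool.** msprime, Binary mutation model, crossover at
  1e-8/bp plus gene conversion (initiation 1e-8/bp, 500 bp tracts). The
  demography follows the structure of the published cosi best-fit model:
  ancestral N = 12,500 splitting ~3,600 generations ago into an African
  branch (N = 24,000) and a European branch with two brief bottlenecks
  (inbreeding ≈ 0.085 each, at ~3,500 and ~2,000 generations) and recent
  exponential expansion from 7,700 to 100,000 over the last 350
  generations; symmetric Africa↔Europe migration at 3e-5/generation.
  The mutation rate (2.05e-8) was calibrated to the target anchors — a
  mean of ~198 polymorphic sites per 10 kb pool with a
  rare(MAF<0.01)/common split of ~166/32, and ~512 per 25 kb — measured
  on pools of 10,000 haplotypes (measured: 200.8 / 163.0 / 37.8 at
  10 kb; 506.9 / 407.2 at 25 kb). Because the anchors are sample-size
  dependent, the pool size is part of the calibration. Mean pairwise r²
  among common variants (MAF > 0.05) in a 10 kb pool is ≈ 0.34.
- **Effects.** Rare class = pool MAF < 0.01. Rare risk variants get
  β = (log 5)/4 · |log10 MAF| (OR = 5 at MAF 1e-4); common risk variants
  get OR ~ Uniform(1.05, 1.3) independent of frequency; protective
  variants get the reciprocal OR. Causal sites are uniform draws within
  class at the scenario's fraction.
- **Penetrance.** P(affected) = expit(α + β·g); α is solved by Brent's
  method so the population prevalence (random haplotype pairs from the
  pool) is 5%.
- **Families.** Parents are two random pool haplotypes each (sampling
  with replacement); children inherit one whole haplotype per parent (no
  intra-region recombination over 10–25 kb); families are
  rejection-sampled on the affection pattern (A: affected child; AA: two
  affected; AUU: exactly one affected of three). Fresh pool, fresh
  effect draw, fresh families per replicate.

What the generator does **not** emulate: sequencing/genotyping error and
missingness, de novo mutation, within-region recombination, non-random
mating, parental phenotypes, gene–environment effects. A green power test
therefore establishes fidelity of the statistical machinery under the
stated generative model, not robustness to data-quality artifacts.

## Desk-scale defaults

The reference experiments used 20,000 (type I) and 1,000 (power)
replicates. The harness defaults are 2,000 and 250, chosen so the whole
acceptance surface runs in minutes on one CPU; exact binomial /
Monte-Carlo error bands in the tests are computed at the scale actually
run. max_K is 20,000 for type I runs (resolution well below 0.01) and
4,000 for power runs (only the p ≤ 0.05 decision matters). Full scale is
available via CLI flags (`--replicates`, `--max-perm`).

## Known limitations

- Nuclear families only; extended pedigrees and missing parents are out
  of scope.
- The ordered-subset gate (min_p ≤ 0.05) makes C discontinuous in the
  data; this is inherent to the method.
- The GRR grid is bounded to (0.5, 20); true effects outside the range
  are clipped to the boundary by construction.
- The mating-type ratio system assumes the minor allele is correctly
  identified; at MAF ≈ 0.5 label flips between permuted datasets are
  possible in principle but irrelevant here because parents are never
  permuted.
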