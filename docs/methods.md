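# Methods

`viropop` studies a naturally segregating pair of multilocus genotypes of
a large double-stranded DNA virus (a nudivirus) infecting wild
*Drosophila*: a "Low" type and a derived "High" type carrying the derived
allele at 11 tightly linked focal SNPs, associated with roughly 100-fold
higher within-host titer. The package provides (i) a synthetic cohort
generator with this structure planted, (ii) the association and
permutation machinery that detects it, (iii) linkage, four-gamete and
haplotype-typing analyses, (iv) McDonald–Kreitman selection statistics,
and (v) a titer-scaled susceptible–infected (SI) evolutionary simulator
for the recurrent origin of the High type. This note records the models,
the defaults and why, and the design choices made where the design was
genuinely open.

## Synthetic cohorts

The generator emulates a field survey of four populations with 57, 92,
92 and 92 flies and infection rates 26, 44, 71 and 79%. Each infected
fly carries one viral genotype (a haploid consensus per locus plus a
within-host derived-allele frequency in [0, 1]).

**Titer model.** log10 titer for a genotype with `k` of `K` focal derived
alleles is Normal(μ(k), σ) with

    μ(k) = μ_low + log10(F) · (1 − λ^k) / (1 − λ^K)

Defaults: μ_low = 3.0 (log10 genome copies per host genome), σ = 0.4,
F = 100 (full High : Low fold difference), λ = 0.7, K = 11. The curve is
geometric-saturation: monotone increasing with strictly decreasing
increments, and μ(K) − μ(0) is exactly log10 F. The observed association
has this diminishing-returns shape but no published functional form;
this is the simplest two-parameter family with the right endpoints.

**Type assignment.** Each infected fly draws a latent type (High with a
population-specific frequency, defaults (0.30, 0.50, 0.71, 0.75) chosen
to correlate with infection rate — the third population matching the
71% High frequency seen in the most intensively sampled site — then
each focal locus flips independently at rate 0.01, producing occasional
intermediate multilocus genotypes with μ(k) titers.

**Background variation**, mirroring the three empirically observed SNP
classes:

- *Population-private, shared between types* (default 15 per
  population): carried by every latent-High sample of one population
  and by a uniform(0.19, 0.94) fraction of that population's Low
  samples — the carriage range reported for such SNPs; absent
  elsewhere. These make viral relatedness partially confound type,
  as in the field data.
- *Shared across populations, High-exclusive* (default 12): carried by
  a uniform(0.2, 0.6) random subset of High samples spanning at least
  two populations, never by Low samples. They are deliberately *not*
  fixed in all High samples: SNPs of this class are described as
  exclusive to, not diagnostic of, the High type, and a locus identical
  to the 11-locus indicator would be indistinguishable from the planted
  haplotype itself.
- *Noise loci* (default 30): per-locus carrier frequency uniform(0.05,
  0.5), independent across samples; the association null.

**Within-host frequencies** of consensus alleles are 1.0 except an
optional segregating locus modeled on the virus's Helicase-2
polymorphism: its frequency is Beta-distributed with the mode following
a bell curve in titer rank (4r(1 − r) for rank fraction r), reflecting
the non-monotone rank relationship seen for that SNP; the concentration
(default 8) is exposed. Sexes, dates and *Wolbachia* flags are uniform
nuisance covariates with no planted effect.

What the generator does **not** emulate: read-level noise, sequencing
error, index switching, within-host diversity beyond the one segregating
locus, host genetic variation, or true coinfection. Passing tests
therefore demonstrate correctness of the statistical machinery on data
with the assumed structure, not robustness to the full messiness of
short-read cohorts.

MK count tables are generated separately: per gene, (Dn, Ds, Pn, Ps) are
Poisson with user-supplied expectations, the Dn mean multiplied by a
per-category inflation (e.g. envelope genes 3×), which plants a positive
Direction of Selection contrast of known direction.

## Association

Per locus the model is ordinary least squares

    log10(titer) ~ SNP + sex + population + SNP:sex + PC1..PCm

on infected samples, with the SNP coded as within-host allele frequency
(continuous; the consensus 0/1 coding falls out automatically for
non-segregating loci). The kinship adjustment is realized as the top
m = 5 eigenvectors of a centered genotype relationship matrix used as
fixed covariates, a transparent stand-in for mixed-model machinery.
Because the dominant axis of viral relatedness *is* the High/Low split,
a relationship matrix built from all loci would absorb the tested signal
(proximal contamination). The relationship matrix for each tested locus
therefore excludes that locus and all loci in strong LD with it
(r² ≥ 0.5, exposed as `grm_exclude_r2`); loci with no LD partner share
one cached global matrix, since self-inclusion there is a 1/L
perturbation. Monomorphic or collinear loci are skipped with a logged
reason — population-private background loci are regularly collinear
with the population covariate, which is expected.

Filtering drops loci whose consensus derived allele occurs in fewer
than 5 infected samples; clumping then greedily merges loci within
10 kb at r² ≥ 0.99 into the lowest-position representative, recording
members. Multiple testing uses Benjamini–Hochberg q values.

Two permutation procedures:

- **min-p threshold**: titer labels permuted across infected samples,
  all loci refit per permutation, the genome-wide minimum p recorded;
  the threshold is the empirical α quantile (α = 0.01, 1000
  permutations by default). This controls family-wise error without an
  independence assumption.
- **haplotype test**: titer permuted *within* populations; per
  permutation the top SNP (or a fixed supplied locus — both modes
  exist because the study describes both) and its 10 most-linked loci
  define a pseudo-haplotype, and the statistic is the mean log-titer
  gap between samples carrying all 11 derived alleles and samples
  carrying none. Empirical p uses the add-one rule, (r + 1)/(n + 1),
  so it is never zero.

Stepwise covariate pruning is not automated: the covariate list is an
explicit argument, because stepwise selection is not reproducibly
specifiable.

## Linkage and haplotypes

r² between haploid consensus calls is the squared Pearson correlation
of 0/1 indicators, identical to D²/(p_A(1−p_A)p_B(1−p_B)); pairs with a
monomorphic locus are undefined (NaN). The four-gamete screen flags
pairs showing all four two-locus combinations. Because one historical
crossover can flag many overlapping pairs, the genome-wide event count
collapses flagged pairs to a maximal set of disjoint intervals (greedy
by right endpoint — the Hudson–Kaplan lower bound); the raw flagged-pair
count is reported alongside, since the two conventions differ and
neither is canonical for a single published genome-wide count. Genome
positions are treated linearly; windows do not wrap the circular genome.

Typing counts focal consensus derived alleles: High iff all, Low iff
none, else intermediate. The consensus threshold is 0.5; the
within-host segregation band is (0.05, 0.95), mirroring the 5% variant
frequency filter. A sample is a suspected coinfection when more than
two focal loci segregate within it — the signature an artificial 50:50
merge of a High and a Low profile produces at every focal locus, which
`merge_profiles` reconstructs for screening calibration.

## McDonald–Kreitman statistics

Sites arrive pre-classified (synonymous/nonsynonymous) with two
outgroup alleles. Polarization requires outgroup agreement; discordant
or unanchorable sites are uninformative. A site is a focal-branch
substitution iff the focal samples are monomorphic for an allele
differing from the shared outgroup state, and a derived polymorphism iff
they vary with the ancestral allele present; singletons (derived count
exactly 1) are removed by default. DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps) is
undefined (reported missing, with reason) when either denominator is
zero. Per-gene contrasts subtract the median of all other genes
(genome-wide scope) or of genes within 100 kb on the same chromosome
(local scope, used for host genes); a background of at least two genes
is required, matching the smallest well-defined case. Category-level
enrichment is a within-category bootstrap (default 10,000 resamples)
of the mean contrast with a percentile 95% interval — a closed-form,
testable replacement for a Bayesian GLMM "selection effect".

## Evolutionary simulator

A discrete-generation SI model in a closed host population of N = 10^6
(dead hosts are replaced by susceptibles, so S + ΣI = N always). The
continuous skeleton is dI/dt = S·I·β − I·γ, whose discrete deterministic
form (`si_deterministic`) converges to I* = 1 − γ/β.

Each infected host carries a genotype over K = 5 ordered loci. Titer
multiplies through gains (10, 3, 2, 1.5, 1.25) along the maximal prefix
of consecutive derived alleles — an out-of-order mutation confers
nothing until its predecessors arrive. The full product, 112.5, sits at
the observed ~100-fold difference with strictly diminishing factors.

Per generation, with T_g the class titer:

1. **Infection**: total force Λ = β0 Σ T_g I_g / N; new infections ~
   Binomial(S, min(1, Λ)), allocated to source classes by multinomial
   with weights T_g I_g. (Per-class binomials with clipped
   probabilities can over-allocate S; the single-draw form has the same
   law at realistic rates and conserves hosts exactly.)
2. **Removal**: per class Binomial(I_g, min(1, γ0 T_g^a)). The
   virulence exponent a (default 0.5) is the one genuinely free
   modeling choice: scaling both infection and removal linearly with
   titer (a = 1) makes the basic reproduction number titer-neutral
   — offspring-per-death is then identical across classes, which the
   suite asserts numerically — so a < 1 is needed for the High type's
   observed net advantage. a = 1 remains available.
3. **Mutation**: each underived locus of each host flips with
   probability min(1, μ·T_g), μ = 3.3e-7 per variant per generation at
   titer 1 (a 1e-6 per-site rate times 1/3 for the correct
   nucleotide). Mutation may occur out of order; there is no
   back-mutation.
4. **Recombination**: infected hosts are paired at random; each of the
   K−1 adjacent intervals independently triggers a suffix swap with
   probability 2%, not scaled with titer. Implementation samples the
   number of swap-active pairs ~ Binomial(I//2, 1 − 0.98^(K−1)),
   assigns pair classes by multinomial on class frequencies (a
   with-replacement approximation of the random matching, repaired in
   the rare oversubscription case) and draws crossover patterns
   conditioned on at least one swap. The suffix-swap transform
   conserves per-pair allele counts, so recombination alone never
   changes marginal allele counts.

States are genotype-class counts over 2^K classes with binomial/
multinomial sampling — the same law as per-individual simulation, at
desk cost for N = 10^6. Runs start from 10% infected all-Low (a 1/N
start is one config field away) and stop at all-loci fixation,
extinction, or 100,000 generations.

**Event recording.** t_first(k) is the first generation with any
carrier of mutation k. t_establish(k) is the first generation the
carrier count reaches 1/(2 s_k), the standard drift-barrier scale, with
s_k = (T_k/T_{k−1})^(1−a) − 1 computed from consecutive-prefix titers;
carriers are counted among genotypes holding the complete prefix 1..k,
because an out-of-order mutant is selectively neutral and cannot escape
drift "under selection" (counting any background makes later
establishment times indistinguishable from first appearances of neutral
mutants and even yields negative waits). An absolute-count rule is
available. t_fix(k) is the first generation mutation-k carrier
frequency among infected reaches 0.99. A replicate is flagged
`recombination_assembled` when the first full-complement genotype is
created by a recombination event rather than a mutation.

**Known limitation.** Under the defaults, mean inter-establishment
waits decrease from mutation 1 through 4 but rise slightly at mutation
5 (≈18 → 21 generations): the smallest gain (1.25×) gives the last
mutation the weakest relative growth rate and the highest drift
barrier, outweighing its larger mutational supply. The monotone
*trend* of waits against index — the quantity the original analysis
tested with a regression — is robustly negative; strict pairwise
monotonicity is not, and the corresponding strict test in the
acceptance suite documents this honestly rather than papering over it.

**Selection arithmetic.** `estimate_selection_coefficient` solves
p1 = p0(1+s)^t; `time_to_frequency` inverts it,
t = ln(p1/p0)/ln(1+s), with years at 5 viral generations per year (a
conservative minimum tied to the host's generation time). Solving
0.99 = 0.0000714·(1.0055)^t gives 1739 generations ≈ 348 years. Note
the two constants are used as printed even though 52% → 71% over 80
generations actually yields s ≈ 0.0039, and 1/(2 N_e s) with N_e = 10^6
and s = 0.0055 would be 9.1e-5, not 7.14e-5; the arithmetic functions
are exact, and reproduce the printed result from the printed inputs.
`joint_mutation_probability` is μ^K: (1e-6/3)^5 = 4.12e-33, the
vanishing chance of all five mutations arising in one generation — the
reason sequential, titer-accelerated evolution is the plausible route.

## Problem sizes and numerics

The acceptance script (`scripts/acceptance.py`) and the end-to-end
tests run the full study-scale configurations: 1000 simulator
replicates at N = 10^6 (about a minute on one core, thanks to the
genotype-class representation) and 100 seeded default surveys through
the whole GWAS pipeline. Calibration properties (type-I error, min-p
threshold coverage, bootstrap coverage) use reduced but still
well-powered designs (hundreds of replicate datasets) with fixed seeds.
All randomness flows from numpy Generators; run-level seeds derive
per-replicate streams via `SeedSequence.spawn`, so replicate r is
independent of how many replicates precede it. Empirical p values use
the add-one rule; quantile thresholds use order statistics
(k = ⌊α·n⌋); OLS uses pseudo-inverse algebra with explicit rank checks,
cross-validated against statsmodels in the tests.
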