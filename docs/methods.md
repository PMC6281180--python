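# Methods

`paleossr` analyzes temporally sampled ("heterochronous") microsatellite
(SSR) genotypes: modern and ancient seed lots scored at the same loci, with
the goal of telling competing demographic histories apart and estimating
their parameters. This note records what the package computes and why the
defaults are what they are.

## Data model

A dataset is a set of diploid individuals, each belonging to exactly one
sample group, scored at a shared panel of SSR loci. Alleles are integer
sizes (repeat units or base pairs); a call is an unordered allele pair;
missing calls are whole-genotype (a half-called genotype is coerced to
missing and counted in the parse report, because a single observed allele
cannot be classified as homozygous or heterozygous without bias). Groups
carry a site, a `modern`/`ancient` type, a calibrated age (`age_calBP`,
with modern = 0) and a seed-color tag used by the admixture scenarios.

The canonical file format is a plain CSV with columns `individual_id,
group, type, site, age_calBP, seed_color` followed by `<LOCUS>.a1/.a2`
pairs. `NA`, `-9`, `0`, `.` and empty cells are missing.

## Diversity statistics

- Observed heterozygosity per locus; Nei's unbiased expected
  heterozygosity `He = n/(n-1) (1 - sum p_i^2)` over observed gene copies.
- Allelic richness standardized by rarefaction: the exact expectation of
  the number of distinct alleles in a subsample of `g` gene copies,
  `sum_a [1 - C(n - N_a, g)/C(n, g)]`, with `g` defaulting to twice the
  smallest per-(group, locus) sample so every group is comparable.
- Multilocus genotype counts (clonal/selfed lineages produce repeats).
- F-statistics by the Weir & Cockerham (1984) variance components,
  summing components over alleles and loci before taking ratios;
  monomorphic loci are omitted from the ratios. A single-sample reduction
  gives within-group Fis; a vectorized two-group version feeds the
  pairwise Fst matrix and the ABC summaries (verified to 1e-10 against an
  independent per-allele ANOVA implementation).
- Goldstein's `(delta mu)^2` between groups (squared difference of mean
  allele size, averaged over shared loci) carries information about
  divergence time under stepwise mutation.
- Equilibrium inversion `s = 2 Fis/(1 + Fis)` converts inbreeding into a
  moment-style selfing estimate.

## Maximum-likelihood selfing estimation

The likelihood-based estimator treats each individual's time since its
last outcrossing event, `t`, as latent with the geometric prior
`P(t) = (1 - s) s^t`. Conditional on `t`, a locus with heterozygosity
frequency `h_l` in outcrossed genotypes is heterozygous with probability
`h_l 2^{-t}` (heterozygosity halves per selfing generation). The marginal
log-likelihood is maximized by EM over `(s, h_1..h_L)`, truncating the
geometric sum where `s^T < 1e-6` (capped at 200) and restarting from
`s in {0.1, 0.5, 0.9}`. Testing `s = 0` is a boundary problem, so the
likelihood-ratio statistic is referred to the mixture
`0.5 chi2_0 + 0.5 chi2_1`. This reference is conservative in finite
samples: with 200 individuals and 24 moderately informative loci only
~14% of null datasets yield a positive statistic (the mixture assumes
50% asymptotically), and the measured size at nominal 5% is ~2.2% over
2000 null replicates. The test under-rejects — the safe direction —
and its power against real selfing remains very high (p < 1e-50 in the
worked examples). A two-sample comparison profiles out the
nuisance `h` per group and tests a shared `s` against free rates (1 df).
A sample with no heterozygous call at all has a monotone likelihood; the
estimate is then reported at the upper search bound (0.999) with a warning.

## Clustering (DAPC)

Genotypes are coded as an individuals x (locus, allele) dosage/2 matrix
(0, 0.5, 1; missing mean-imputed), reduced by centered PCA (retaining
enough axes for 90% of the variance, capped at n/3), clustered by k-means
over a range of k scored by `BIC(k) = n ln(WSS/n) + k ln(n)`, and the
cluster labels are re-described by linear discriminant analysis to give
per-individual assignment probabilities. Two caveats are deliberate:
the BIC curve of k-means on low-dimensional scores keeps decreasing past
the visually obvious k when clusters are strong (a known property of this
criterion), so a user-forced `k` is honored and the BIC curve is always
returned for inspection; and the LDA falls back to a shrinkage solver when
the within-group covariance is singular.

## Coalescent simulator

Genealogies are simulated backward in time in a structured coalescent with
partial selfing and serial sampling:

- Each diploid contributes two lineages at its group's sampling time (ages
  converted to generations; the crop is annual so one year = one
  generation by default). Selfing is handled by the standard two-phase
  approximation: the pair coalesces instantly at sampling with probability
  `F = s/(2 - s)`, and surviving pairs in a pool of size `Ne` and selfing
  rate `s` coalesce pairwise at rate `(1 + F)/(2 Ne)` — the classical
  effective-size rescaling `Ne/(1 + F)`.
- Demography is a set of pools with divergence events (all lineages of a
  child pool move to its parent) and, for the admixture scenario, a pulse
  that reassigns each lineage of a named sample to the wild pool with
  probability `r_wild` at its sampling time. Every history terminates in
  an explicit ancestral pool, which makes priors and validation uniform.
- Mutations follow the generalized stepwise model: Poisson counts with
  rate `mu` per branch generation, geometric step magnitudes (parameter
  `p_geom`; 0 = strict stepwise), equiprobable sign, reflecting at the
  allele-size bounds (default 5–50 repeat units) with the root at the
  midpoint.
- Each locus gets an independent genealogy, including independent
  instantaneous-selfing draws. This ignores identity disequilibrium (the
  across-locus correlation of heterozygosity in partially selfed
  pedigrees), which slightly narrows the across-locus variance of
  simulated Fis; the ML selfing estimator is validated on a forward
  pedigree simulator that does model it.

Correctness checks: pairwise TMRCA within 2% of `2 Ne` over 1e4
genealogies; the full TMRCA distribution matches `msprime` for a single
pool (Kolmogorov–Smirnov); equilibrium He under strict stepwise mutation
within 0.03 of `1 - 1/sqrt(1 + 8 Ne mu)`.

## Competing scenarios

Six nested-to-divergent histories for a design with modern, intermediate
(younger than 1000 BP) and ancient (1000+ BP) sample tiers:

- **A** — drift only: all samples serial in one pool.
- **B** — the modern pool replaced the pool of all older samples.
- **C** — a recent pool (modern + intermediate) replaced the old pool.
- **D** — successive replacement: modern ← intermediate ← ancient chain.
- **E** — D plus a wild pool; dark-seeded samples are drawn from it.
- **F** — E, but dark-seeded samples are drawn from their sympatric
  cultivated pool with an admixture pulse (proportion `r_wild`) from the
  wild pool at their sampling time.

## ABC random forest

Inference follows the ABC-RF scheme: simulate a reference table of
(scenario, parameters, summaries), train a random-forest classifier on the
summaries, and read off (i) per-tree votes for the observed dataset,
(ii) the prior error rate as the out-of-bag misclassification rate, and
(iii) the posterior probability of the selected scenario as the prediction
of a regression forest trained on out-of-bag correctness indicators.
Parameters of the selected scenario are estimated by per-parameter
regression forests; point estimate = forest prediction, interval = 2.5/97.5%
weighted quantiles of the training responses with leaf co-occurrence
weights.

Summaries (length `5G + 2 C(G,2)` for `G` groups): per group He, mean
allele count, allele-size variance, proportion of monomorphic loci and
Fis; per pair WC Fst and `(delta mu)^2`. He counts monomorphic loci as 0
rather than dropping them so the vector stays defined for low-diversity
simulations; undefined entries (e.g. Fis of an all-missing group) are set
to a sentinel 0, identically in training and observation.

Default priors: `Ne ~ logU(10, 1e4)` per pool; divergence times
`logU(max(dependent sample age, 10), 1e4)` with ordering constraints
enforced by rejection; `s ~ U(0,1)` per pool; `mu ~ logU(1e-4, 1e-3)`;
`p_geom ~ U(0, 0.6)`; `r_wild ~ U(0,1)`. The observed per-group
missingness process is imposed on every simulated dataset so the summaries
are compared like with like.

## Scale of the shipped experiments

Tests and the bundled acceptance script run on a single CPU in minutes, so
they use desk-scale reference tables (hundreds to 2000 simulations per
scenario, 24 loci) rather than publication-scale tables (tens of
thousands per scenario). This is a deliberate default of the package;
accuracy numbers printed by the script are for the desk scale and improve
with table size. One simulation costs ~0.03 s at the default design, so
publication-scale tables are a few CPU-hours.

## Synthetic data

Two generators are independent of the coalescent machinery and serve as
oracles for the estimators: a Dirichlet-frequency generator with explicit
within-group inbreeding `F` (autozygous with probability `F`), and a
forward pedigree generator that draws each individual's selfing age from a
geometric distribution and halves heterozygosity per generation. A missing
-data injector applies per-group missing-completely-at-random masks.
A bundled 19-group / 157-seed survey design (81 modern seeds in 12 groups,
76 ancient in 7, high inbreeding, elevated ancient missingness, 24 loci)
emulates the shape of a real mixed modern/ancient germplasm survey; a
7-group temporal design (ages 0–1796 BP, two dark-seeded groups) drives
the scenario machinery.
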