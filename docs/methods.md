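# Methods

`seedfit` re-implements, as one reproducible pipeline, the analysis chain
that links the fitness of open-pollinated tree seedlings to the genetic
heterogeneity of their parent pair: admixture clustering of microsatellite
genotypes, likelihood-based paternity assignment, maximum-likelihood
pairwise relatedness, the two bi-parental ancestry statistics *qdis* and
*fdis*, proportional-hazards survival modelling and a Bayesian growth model.
Because the pipeline is meant to be validated end to end, a forward
simulator of the whole study design is a first-class component: it generates
genotypes, matings and fitness data with known truth, and every downstream
stage is tested as a recovery experiment against that truth.

## The admixture model and its sampler

Genotypes are diploid and unphased at L unlinked microsatellite loci.
Under the correlated-allele-frequency admixture model ("F-model"), cluster
k's allele frequencies at locus l drift from a shared ancestral vector:

    P_kl | P_A,l, F_k  ~  Dirichlet( P_A,l * (1 - F_k) / F_k ),

so F_k is interpretable as cluster k's Fst from the ancestral admixed
population. Individual i has an ancestry vector Q_i ~ Dirichlet(alpha) on
the K-simplex, and each allele copy picks a cluster Z from Q_i and then an
allele from P_Z.

Inference is MCMC: Z, P and Q have conjugate Gibbs updates; P_A (per-locus
pairwise mass transfer, step sd 0.05), F_k (random walk, step sd 0.02,
truncated-normal(0.01, 0.05) prior on (0,1)) and the single shared alpha
(random walk, step sd 0.025, uniform(0,10) prior) use Metropolis steps. The
ancestral-frequency Dirichlet parameter lambda is fixed at 1. Missing loci
are skipped in all count updates. The per-sweep data log-likelihood is
recorded every 10th sweep after burn-in.

Model evidence per K uses the harmonic-approximation estimator
L(K) = mean(lnL) − var(lnL)/2, and the number of clusters is chosen by the
Evanno second-difference statistic ΔK(K) = |L(K+1) − 2 L(K) + L(K−1)| /
sd(L(K)) over replicate runs, with endpoints reported as NA. Replicates of
the selected K are label-aligned by a greedy column matching that maximises
summed dot products with a reference run (ties broken toward the lowest
column index), and the consensus Q is the mean of the aligned matrices.

Production defaults are 50,000 burn-in + 100,000 recorded-phase sweeps,
5 replicates over K = 1–6; the test suite and the worked examples use
2,000 + 8,000 scaled-down sweeps, which on the default synthetic data give
the same Q to within MCMC error (~1 ms/sweep for n = 182, L = 10).

Two caveats established by experiment (both documented in the test suite):

* With the default generating conditions — drift (0.10, 0.01, 0.10), 182
  adults, 10 loci of ~8 alleles — the ancestry matrix is only partially
  identifiable: the posterior computed with the *true* cluster frequencies
  has a mean absolute Q error of ≈ 0.16, because the weakly drifted second
  cluster is nearly indistinguishable from the ancestral pool. The sampler
  operates close to that ceiling (≈ 0.18); tests therefore compare against
  the known-parameter oracle, not an absolute error target.
* ΔK selection is unstable on such data: the evidence gain from K = 1 to
  K = 2 dwarfs the gain from adding the weak third cluster, so the second
  difference often favours the top hierarchical split (K = 2) — the
  well-known conservative bias of ΔK — or lands elsewhere when replicate
  sds are erratic, even though L(K) itself tends to peak at K = 3.
  Consensus clustering is therefore run at a fixed K in the pipeline when
  the user supplies one, and ΔK output should be read alongside the L(K)
  column it is derived from.

## Paternity assignment

For offspring o with known mother m, every plot adult c (the mother
included — that is how selfing is detected) receives a LOD score

    LOD(c) = sum over shared typed loci of
             ln[ P(g_o | g_m, g_c, e) / P(g_o | g_m) ],

with the standard codominant transition probabilities. Genotyping error
enters as a per-genotype mistyping rate e: the observed offspring genotype
is, with probability e, an unrelated Hardy–Weinberg draw, so one Mendelian
incompatibility no longer forces −inf (it does at e = 0). The statistic
Δ = LOD(1st) − LOD(2nd) is calibrated by simulating offspring of known
paternity from the estimated allele frequencies and returning the smallest
threshold at which ≥ 95% of assignments exceeding it are correct; ties
(Δ = 0) never support an assignment. Categories are assigned by ordered
rules: selfing (mother wins and passes Δ), immigrant (best candidate has
more than 2 mismatches in the simple exclusion procedure), ambiguous
(Δ below critical), else single donor. The category counts partition the
cohort exactly — the accounting identity asserted in tests.

Two empirical properties of the default synthetic conditions are worth
knowing. First, with the mother known and ten 8-allele loci, the markers are
powerful enough that ≥ 95% of top assignments are already correct at any
Δ > 0, so the calibrated threshold is 0; a positive threshold appears as
soon as marker power drops (e.g. ≈ 1.4 with only three loci). Second,
immigrant detection by the >2-mismatch rule catches only ~a third of true
immigrant-sired seedlings at this allele diversity, because the best of 182
in-plot candidates often shows ≤ 2 mismatches by chance; the rule itself is
exact, the detection *rate* is a property of marker information content.

Allele frequencies are estimated from adults and offspring jointly with a
pseudo-count of 0.5 per observed allele (configurable), which keeps alleles
seen only in offspring at positive frequency. Half-typed loci are coerced
to fully missing (with a logged warning) everywhere, since all likelihoods
assume a locus is typed or not as a unit. The dense per-locus genotype
tables used for vectorised scoring are O(A^6) in the allele count A and are
capped at A = 16; rarer-allele data should be binned first.

## Pairwise relatedness

Relatedness between mother and assigned father is estimated by maximum
likelihood over the IBD coefficients (k0, k1, k2) of a non-inbred pair,
with per-locus likelihood k0·S0 + k1·S1 + k2·S2 (S_m the probability of the
observed unordered genotype pair given m shared alleles), and r = k1/2 + k2.
The optimum is a 0.01-step grid scan over the simplex with 10× local
refinement; an independent fine-grid scan in the tests confirms the optimum
to within 0.01 in r. Inbreeding and null-allele corrections are out of
scope; panels with suspected null alleles should be screened before use. The estimator is
boundary-biased upward for truly unrelated pairs: at 10 equifrequent
8-allele loci the mean estimate is ≈ 0.06 rather than 0 (parent–offspring
pairs are recovered at ≈ 0.52); an optional pedigree constraint
k1² ≥ 4·k0·k2 reduces the bias marginally.

## qdis, fdis and the covariate table

For a parent pair (i, j) with ancestry vectors Q_i, Q_j:

    qdis_ij = sqrt( sum_k (Q_ik − Q_jk)^2 / 2 )        (Rogers' distance)
    fdis_ij = sum_k (Q_ik + Q_jk) · fst_k / 2,

where fst is a *signed* per-cluster differentiation vector. qdis is a metric
on the simplex (property-tested); fdis is linear in each argument and, with
a contrast of the form (c, 0, −c), vanishes for pure cluster-1 × cluster-3
pairs — the "opposing poles" construction. Because the admixture model can
only produce positive drift values, the signed vector is a configuration
input (default (0.10552, 0.00044, −0.10342), the field estimates); a helper
maps an estimated F vector to a signed contrast by negating the
higher-indexed of the two most-drifted clusters. A no-square-root variant of
qdis is available behind a flag for sensitivity analysis.

The covariate table keeps only seedlings with a single identified in-plot
donor and joins seed weight w (grams), relatedness r, qdis and fdis;
excluded-category counts are logged so the cohort bookkeeping can be
asserted downstream.

## Survival model

Census tables are coded to one (time, event) record per seedling: event
time is the first census recorded dead, survivors are right-censored at the
last census, and a dead-then-alive sequence is an error. Time is measured
on the census index by default (the weekly-then-monthly calendar makes
calendar time heterogeneous; a flag switches to days).

The Cox proportional-hazards model is maximised by Newton–Raphson on the
partial likelihood with Efron (default) or Breslow tie handling;
standard errors come from the inverse observed information, and the fit is
cross-checked against an independent survival package in the tests. Model
comparison covers the standard 11-model family over {w, r, qdis|fdis}
(the two ancestry statistics are alternative parameterisations of one
contrast and never co-occur), reporting AIC = −2·pl + 2p,
BIC = −2·pl + p·ln(events) (events as the effective sample size, the usual
survival convention) and deviance; p is the number of covariates.
A monotone likelihood (perfect separation, possible on very small cohorts)
raises an error, or skips the model in whole-family fits inside the
pipeline. Kaplan–Meier curves grouped by qdis (cuts 0.1, 0.35) or fdis
(cuts 0.02, 0.035) are computed through lifelines.

## Growth model

Heights are differenced into per-period relative growth rates
RGR = ln(H_t/H_{t−1})/(T_t − T_{t−1}) in day⁻¹, with periods defined by the
global measurement schedule (a seedling missing either endpoint contributes
no record). Each period is modelled as

    RGR_s = b0 + b_stat·stat_s + b_r·r_s + b_w·w_s + u_g(s) + eps_s,

eps ~ N(0, σ²), u ~ N(0, τ²), with priors N(0, 10²) on coefficients and
InverseGamma(0.001, 0.001) on both variances — all conjugate, so the
sampler is plain Gibbs with a sum-to-zero recentring of u each sweep (the
grand mean of u is exchanged with the intercept, removing their joint flat
direction). The grouping is the mother tree by default: with one
observation per seedling per period, a per-seedling intercept is confounded
with the residual and is only weakly identified by its proper prior; it
remains available behind `group="seedling"` since the original analysis
appears to have used a per-individual effect. Defaults are 3 chains ×
150,000 sweeps with 30,000 burn-in; tests use 2–3 chains × ~1,200–4,000.
Convergence is summarised by split-chain potential scale reduction
(R̂ = sqrt(((n−1)/n·W + B/n)/W)); frozen chains at different values report
+inf, and an effect is called non-zero when its 95% credible interval
excludes zero.

## The synthetic-data generator

The generator emulates the study design end to end with one seeded RNG:

* **Adults** — 182 individuals, 10 loci, 8 alleles per locus; ancestral
  frequencies symmetric-Dirichlet(1), cluster frequencies from the F-model
  with drift (0.10, 0.01, 0.10), ancestry vectors Dirichlet(0.2) (mostly
  near-pure individuals with an admixed minority).
* **Matings** — 6 mother trees × 98 seeds (588 seeds); selfing fraction
  0.09 and immigrant-pollen fraction 0.10, back-calculated from the realized
  category proportions of the cohort the design mirrors (41/460 and 48/460);
  outcross fathers uniform among the other adults; immigrant fathers drawn
  from the ancestral frequencies (the simplest model of out-of-plot pollen);
  Mendelian inheritance with optional per-allele mistyping.
* **Fitness** — seed weight lognormal (mean 1 g, sd 0.25 on the log scale),
  independent of genotype by default (a switch couples it to the mother for
  sensitivity runs); survival follows a discrete-time proportional-hazards
  process with per-census death probability 1 − exp(−h0·exp(x'β)), h0 = 0.02
  over 30 monthly censuses (≈ 30–45% cumulative baseline mortality —
  nursery-scale attrition) and default β = (0, 0, −3.4) on (w, r, qdis), the
  reported hazard coefficient; heights start lognormal around 15 cm and grow
  log-linearly with per-period RGR = 0.003 + 0.0015·qdis + u + eps
  (τ = 5·10⁻⁴, σ = 8·10⁻⁴ day⁻¹), measured at six-monthly censuses.

Truth (ancestry vectors, pedigree, category, covariates, linear predictors)
is retained in a `TruthBundle` for recovery tests. What the generator does
*not* emulate — and what passing tests therefore do not establish for real
data: spatial pollen dispersal and fine-scale geography, linkage and
mutation, null alleles and locus-specific error, inbreeding in the adult
stand, germination as a process (germination counts are input data only),
and environmental covariates of survival. Real microsatellite panels also
tend to carry more alleles per locus than the simulated 8, which improves
paternity exclusion and relatedness accuracy relative to the synthetic
setting.

## Numerical choices and degenerate inputs

* Frequency smoothing: pseudo-count 0.5 per observed allele; with smoothing
  0 an unseen allele has probability 0 and acts as a hard exclusion.
* Dirichlet sampling uses gamma draws floored at 1e-300 before
  normalisation so log-densities stay finite.
* Cox Newton–Raphson: step-halving on likelihood decrease, divergence
  declared at |β| > 50; gradient at the optimum is asserted < 1e-6.
* Relatedness grid: 0.01 step plus 0.001 local refinement; ties in the
  greedy label alignment break toward the lowest column index.
* ΔK with zero replicate variance is reported as +inf with a warning;
  endpoints of the K range are never selection candidates.
* Determinism: every stochastic stage takes a seed spawned from the global
  run seed via `SeedSequence`; artifacts are written with fixed float
  formatting and sorted JSON keys, so identical configs produce
  byte-identical outputs.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run the full default cohort
(182 adults, 588 seeds) for simulation-based checks, scaled-down MCMC for
clustering (2,000 + 8,000 sweeps × 5 replicates × K = 1–6), 10,000
calibration simulations for paternity, 20 replicate cohorts for the Cox
recovery, 200 pairs per relatedness condition, and 40 replicates × 2 chains
× 1,200 sweeps for the growth-model calibration.

## Known limitations

* The admixture sampler records a single chain per run; within-run label
  switching is not corrected (it was not observed on the shipped data
  sizes, where modes are well separated).
* The dense paternity tables limit loci to ≤ 16 alleles.
* The growth model assumes Gaussian RGR with homoskedastic residuals per
  period; no model comparison across growth models is provided.
* Frailty (random-effect) survival models, time-varying covariates and
  interval censoring are out of scope; the survival model family is
  fixed-effects only.
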