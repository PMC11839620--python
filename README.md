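# seedfit

Tools for asking a population-genetics question about forest regeneration:
**do seedlings whose parents carry different ancestral genetic backgrounds
survive and grow better than seedlings of genetically similar parents?**
The package targets studies of tropical tree stands — the motivating system
is a dipterocarp (*Rubroshorea curtisii*) hill forest where mature trees
fall into admixed genetic clusters — but every stage works on generic
diploid microsatellite data: a genotype table of candidate parents, a
genotype table of nursery seedlings with known mothers, and seed-weight /
survival / height census tables.

The pipeline chains six analyses:

1. **Admixture clustering** (Gibbs/Metropolis MCMC under the
   correlated-allele-frequency F-model) — ancestry vectors Q_i, per-cluster
   drift F_k, model choice by the Evanno ΔK statistic, replicate alignment.
2. **Paternity assignment** — CERVUS-style LOD scores with a
   simulation-calibrated Δ confidence threshold and a mismatch-based
   exclusion rule, yielding the categories selfing / immigrant / ambiguous /
   single donor.
3. **Relatedness** — maximum-likelihood IBD coefficients (k0, k1, k2) per
   mother-father pair, r = k1/2 + k2.
4. **Bi-parental ancestry statistics** — for a parent pair (i, j),

       qdis_ij = sqrt( Σ_k (Q_ik − Q_jk)² / 2 )          (Rogers' distance)
       fdis_ij = Σ_k (Q_ik + Q_jk) · fst_k / 2           (signed-drift weight)

5. **Survival** — Cox proportional hazards (Efron/Breslow ties, Newton–
   Raphson on the partial likelihood) over the model family
   {w, r, qdis|fdis}, compared by AIC/BIC/deviance, plus grouped
   Kaplan–Meier curves.
6. **Growth** — per-period relative growth rates
   RGR = ln(H_t/H_{t−1})/(T_t−T_{t−1}) fitted with a Gibbs-sampled Bayesian
   linear mixed model (random mother-tree intercept), summarised with
   split-chain R̂.

A forward simulator of the whole study design (`seedfit.simulate`) generates
genotypes, matings (with selfing and immigrant pollen) and fitness data with
known truth, so the entire chain is testable as a recovery experiment.
See `docs/methods.md` for the models, priors and design choices.

## Worked example

Simulate a default study (182 adults in 3 clusters, 6 mothers × 98 seeds,
9% selfing, 10% immigrant pollen) and run the full pipeline:

```python
from seedfit.pipeline import run_pipeline

manifest = run_pipeline({
    "seed": 5,
    "outdir": "scratch/demo",
    "simulate": {},                       # default study conditions
    "cluster": {"k_fixed": 3, "reps": 2, "burnin": 2000, "iters": 8000},
    "parentage": {"n_sim": 10000},
    "growth": {"chains": 3, "iters": 4000, "burnin": 1000},
})
print(manifest["counts"])
```

which prints (exact numbers for this seed):

```
{'n_adults': 182, 'n_seedlings': 588, 'k_selected': 3,
 'categories': {'immigrant': 30, 'selfing': 54, 'single_donor': 504},
 'delta_crit_95': 0.0, 'n_parent_pairs': 409, 'n_covariate_rows': 504,
 'n_events': 76, 'n_growth_records': 2246}
```

Reading this: of 588 seedlings, 54 were classed as selfed and 30 as sired
by out-of-plot pollen; 504 got a single confident in-plot father (the Δ
threshold calibrated to 0 because ten 8-allele loci with a known mother
resolve >95% of cases at any positive Δ, so no seedling was left
ambiguous). Those 504 seedlings, their 76 deaths over 30 monthly censuses
and 2,246 six-monthly growth records feed the survival and growth models. `scratch/demo/` then contains the Q
matrix, parentage table, covariates (w, r, qdis, fdis), the Table-style Cox
model comparison (`survival_models.csv`), Kaplan–Meier curves grouped by
qdis/fdis, and per-period growth posteriors.

In the shipped synthetic cohorts the Cox coefficient on qdis recovers its
generating value −3.4 (mean fitted −3.44 over 20 replicate cohorts, always
negative): seedlings of genetically *similar* parents (small qdis) die at a
higher rate — the negative frequency-dependent-selection signature the
pipeline is built to detect.

Every stage is also exposed on the command line (`seedfit simulate`,
`cluster`, `parentage`, `relatedness`, `survival`, `growth`,
`seedfit run --config run.yaml`); each flag maps 1:1 to a config key.

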