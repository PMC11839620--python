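"""Forward simulator for the whole study design.

Generates (1) admixed adult genotypes under the correlated-allele-frequency
F-model, (2) open-pollinated seed arrays with selfing and immigrant pollen,
and (3) seedling fitness data — monthly survival censuses from a
discrete-time proportional-hazards model and six-monthly height censuses from
a log-linear growth model with a per-seedling random intercept.  Every draw
flows from one :class:`numpy.random.Generator`, so a run is fully reproducible
from ``SimConfig.rng_seed``.  The accompanying :class:`TruthBundle` records
the latent state (ancestry vectors, pedigree, category, linear predictors)
that downstream recovery tests compare against.
"""
from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeTable, PhenotypeTable

#: default marker names (ten nuclear microsatellites)
DEFAULT_LOCI = ["shc04", "shc07", "shc09", "sle074", "sle384",
                "sle392", "sle562", "sle566", "slu044", "slu175"]


@dataclasses.dataclass
class SimConfig:
    """Study-design parameters for the forward simulation.

    Defaults emulate the field design: 3 genetic clusters with drift
    (0.10, 0.01, 0.10) from the ancestral admixed pool, 182 adults typed at
    10 loci with ~8 alleles each, 6 mother trees with ~98 seeds apiece
    (588 seeds), a selfing fraction of 0.09 and an immigrant-pollen fraction
    of 0.10 (back-calculated from realized cohort counts 41/460 and 48/460).
    """

    k: int = 3
    n_loci: int = 10
    alleles_per_locus: int = 8
    drift: tuple = (0.10, 0.01, 0.10)
    admix_alpha: float = 0.2
    n_adults: int = 182
    n_mothers: int = 6
    seeds_per_mother: int = 98
    selfing_rate: float = 0.09
    immigrant_rate: float = 0.10
    mistyping_rate: float = 0.0
    # seed weight: lognormal, mean 1 g on the natural scale, sd 0.25 on log scale
    seed_weight_logmean: float = 0.0
    seed_weight_logsd: float = 0.25
    couple_seed_weight_to_mother: bool = False
    # survival: discrete-time proportional hazards over monthly censuses
    baseline_hazard: float = 0.02
    n_censuses: int = 30
    census_interval_days: int = 30
    surv_beta_w: float = 0.0
    surv_beta_r: float = 0.0
    surv_beta_stat: float = -3.4
    surv_stat: str = "qdis"
    # growth: RGR (day^-1) = intercept + b_stat*stat + b_r*r + b_w*w + u + eps
    growth_intercept: float = 0.003
    growth_beta_stat: float = 0.0015
    growth_beta_r: float = 0.0
    growth_beta_w: float = 0.0
    growth_tau: float = 5e-4
    growth_sigma: float = 8e-4
    growth_stat: str = "qdis"
    height0_logmean: float = math.log(15.0)
    height0_logsd: float = 0.15
    height_days: tuple = (60, 240, 420, 600, 780, 960)
    rng_seed: int = 0

    def __post_init__(self):
        self.drift = tuple(self.drift)
        if len(self.drift) != self.k:
            raise ValueError("drift must have one entry per cluster")
        if any(not (0.0 < f < 1.0) for f in self.drift):
            raise ValueError("drift values must lie strictly in (0, 1)")
        for name in ("selfing_rate", "immigrant_rate", "mistyping_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.selfing_rate + self.immigrant_rate > 1.0:
            raise ValueError("selfing_rate + immigrant_rate must not exceed 1")
        if self.n_mothers > self.n_adults:
            raise ValueError("n_mothers cannot exceed n_adults")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be non-negative")
        if self.surv_stat not in ("qdis", "fdis") or self.growth_stat not in ("qdis", "fdis"):
            raise ValueError("surv_stat / growth_stat must be 'qdis' or 'fdis'")

    @property
    def signed_fst(self) -> np.ndarray:
        """Signed drift contrast used for the true fdis covariate.

        Clusters 1 and K act as opposing poles: the last cluster's drift is
        negated so that pure-1 x pure-K matings have near-zero fdis.
        """
        v = np.array(self.drift, dtype=float)
        if self.k > 1:
            v[-1] = -v[-1]
        return v


@dataclasses.dataclass
class TruthBundle:
    """Latent simulation state used as the oracle in recovery tests."""

    adult_q: pd.DataFrame = None          # index id, columns Q1..QK
    ancestral_freqs: np.ndarray = None    # (L, A)
    cluster_freqs: np.ndarray = None      # (K, L, A)
    allele_codes: np.ndarray = None       # (A,) integer codes
    mothers: list = None
    parents: pd.DataFrame = None          # seedling_id, mother_id, father_id, category
    covariates: pd.DataFrame = None       # seedling_id, w, r, qdis, fdis, ...

    def write_json(self, path) -> None:
        payload = {
            "mothers": self.mothers,
            "adult_q": self.adult_q.reset_index().to_dict(orient="list"),
            "parents": self.parents.to_dict(orient="list")
            if self.parents is not None else None,
            "covariates": self.covariates.to_dict(orient="list")
            if self.covariates is not None else None,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, default=str))


def _draw_genotype_from_freqs(rng, freqs_la: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg draw: (L, 2) allele *indices* given (L, A) frequencies."""
    L, A = freqs_la.shape
    u = rng.random((L, 2, 1))
    cdf = np.cumsum(freqs_la, axis=1)[:, None, :]
    return (u > cdf).sum(axis=2)


def simulate_adults(cfg: SimConfig, rng: np.random.Generator = None):
    """Draw admixed adult genotypes under the correlated-frequency model.

    Ancestral frequencies per locus are symmetric-Dirichlet(1); cluster k's
    frequencies are Dirichlet(p_anc * (1-F_k)/F_k); ancestry vectors Q_i are
    Dirichlet(admix_alpha); each allele copy samples a cluster from Q_i and
    then an allele from that cluster's frequencies.
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    K, L, A, n = cfg.k, cfg.n_loci, cfg.alleles_per_locus, cfg.n_adults
    p_anc = rng.dirichlet(np.ones(A), size=L)                      # (L, A)
    cluster = np.empty((K, L, A))
    for k in range(K):
        ratio = (1.0 - cfg.drift[k]) / cfg.drift[k]
        for l in range(L):
            cluster[k, l] = rng.dirichlet(np.maximum(p_anc[l] * ratio, 1e-6))
    Q = rng.dirichlet(np.full(K, cfg.admix_alpha), size=n) if K > 1 \
        else np.ones((n, 1))
    u = rng.random((n, L, 2, 1))
    z = (u > np.cumsum(Q, axis=1)[:, None, None, :]).sum(axis=3)
    ua = rng.random((n, L, 2, 1))
    cdf_k = np.cumsum(cluster, axis=2)                              # (K, L, A)
    a_idx = (ua > cdf_k[z, np.arange(L)[None, :, None], :]).sum(axis=3)
    codes = 100 + 2 * np.arange(A)
    ids = [f"A{i:03d}" for i in range(1, n + 1)]
    g = GenotypeTable(ids=ids, groups=["plot"] * n,
                      loci=list(DEFAULT_LOCI[:L]) if L <= len(DEFAULT_LOCI)
                      else [f"loc{j:02d}" for j in range(L)],
                      alleles=codes[a_idx])
    mothers = sorted(rng.choice(ids, size=cfg.n_mothers, replace=False).tolist())
    truth = TruthBundle(
        adult_q=pd.DataFrame(Q, index=ids,
                             columns=[f"Q{k+1}" for k in range(K)]),
        ancestral_freqs=p_anc, cluster_freqs=cluster,
        allele_codes=codes, mothers=mothers,
    )
    return g, truth


def simulate_matings(adults: GenotypeTable, truth: TruthBundle,
                     cfg: SimConfig, rng: np.random.Generator = None):
    """Generate seed arrays per mother with selfing and immigrant pollen.

    Each seed is, with probability ``selfing_rate``, selfed; with probability
    ``immigrant_rate`` sired by a fresh Hardy-Weinberg genotype drawn from the
    ancestral frequencies (a pollen donor outside the candidate list);
    otherwise sired by a plot adult chosen uniformly (excluding the mother).
    Offspring inherit one Mendelian allele per parent per locus; each allele
    copy is independently mistyped with probability ``mistyping_rate`` (the
    recorded code is replaced by a random allele at that locus).
    """
    rng = np.random.default_rng(cfg.rng_seed + 1) if rng is None else rng
    L, A = cfg.n_loci, cfg.alleles_per_locus
    codes = truth.allele_codes
    code_to_idx = {int(c): i for i, c in enumerate(codes)}
    adult_idx = {iid: i for i, iid in enumerate(adults.ids)}
    # adult genotypes as allele indices
    vec = np.vectorize(code_to_idx.get)
    adult_ai = vec(adults.alleles)

    rows, ids, parents = [], [], []
    sn = 0
    for mother in truth.mothers:
        mi = adult_idx[mother]
        for _ in range(cfg.seeds_per_mother):
            sn += 1
            sid = f"S{sn:04d}"
            u = rng.random()
            if u < cfg.selfing_rate:
                category, father = "selfing", mother
                father_ai = adult_ai[mi]
            elif u < cfg.selfing_rate + cfg.immigrant_rate:
                category, father = "immigrant", None
                father_ai = _draw_genotype_from_freqs(rng, truth.ancestral_freqs)
            else:
                category = "outcross"
                others = [a for a in adults.ids if a != mother]
                father = others[rng.integers(len(others))]
                father_ai = adult_ai[adult_idx[father]]
            mat = adult_ai[mi][np.arange(L), rng.integers(2, size=L)]
            pat = father_ai[np.arange(L), rng.integers(2, size=L)]
            geno = np.stack([mat, pat], axis=1)
            if cfg.mistyping_rate > 0:
                err = rng.random((L, 2)) < cfg.mistyping_rate
                geno[err] = rng.integers(A, size=int(err.sum()))
            ids.append(sid)
            rows.append(codes[geno])
            parents.append((sid, mother, father, category))
    seedlings = GenotypeTable(
        ids=ids, groups=[p[1] for p in parents], loci=list(adults.loci),
        alleles=np.array(rows, dtype=np.int64),
    )
    truth.parents = pd.DataFrame(
        parents, columns=["seedling_id", "mother_id", "father_id", "category"]
    )
    return seedlings, truth


def _true_covariates(truth: TruthBundle, cfg: SimConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Per-seedling (w, r, qdis, fdis) from the latent pedigree and Q."""
    from .parental_stats import qdis as _qdis, fdis as _fdis

    K = cfg.k
    Q = truth.adult_q
    center = np.full(K, 1.0 / K)       # immigrant donor: undifferentiated pool
    signed = cfg.signed_fst
    recs = []
    for sid, mother, father, category in truth.parents.itertuples(index=False):
        if cfg.couple_seed_weight_to_mother:
            # deterministic per-mother offset for sensitivity runs
            off = 0.1 * (sum(map(ord, mother)) % 5 - 2) / 2.0
        else:
            off = 0.0
        w = float(np.exp(rng.normal(cfg.seed_weight_logmean + off,
                                    cfg.seed_weight_logsd)))
        qm = Q.loc[mother].to_numpy()
        qf = center if father is None else Q.loc[father].to_numpy()
        r = 1.0 if category == "selfing" else 0.0
        recs.append((sid, mother, father, category, w, r,
                     _qdis(qm, qf), _fdis(qm, qf, signed)))
    return pd.DataFrame(recs, columns=["seedling_id", "mother_id", "father_id",
                                       "category", "w", "r", "qdis", "fdis"])


def simulate_fitness(seedlings: GenotypeTable, truth: TruthBundle,
                     cfg: SimConfig, rng: np.random.Generator = None):
    """Simulate survival and height censuses for every seedling.

    Survival: at each census a living seedling dies with probability
    ``1 - exp(-h0 * exp(x'beta))``, the discrete-time analogue of a
    proportional-hazards model with constant baseline hazard per census.
    Growth: per-period RGR = intercept + b_stat*stat + b_r*r + b_w*w + u + eps
    with u ~ N(0, tau^2) per seedling and eps ~ N(0, sigma^2) per period;
    heights are integrated as H_t = H_{t-1} * exp(RGR * dt) and recorded only
    while the seedling is alive at the measurement day.
    """
    rng = np.random.default_rng(cfg.rng_seed + 2) if rng is None else rng
    cov = _true_covariates(truth, cfg, rng)
    truth.covariates = cov

    stat_s = cov[cfg.surv_stat].to_numpy()
    lp = (cfg.surv_beta_w * cov["w"].to_numpy()
          + cfg.surv_beta_r * cov["r"].to_numpy()
          + cfg.surv_beta_stat * stat_s)
    n = len(cov)
    death_census = np.full(n, np.inf)
    alive = np.ones(n, dtype=bool)
    surv_rows = []
    p_die = 1.0 - np.exp(-cfg.baseline_hazard * np.exp(lp))
    for t in range(1, cfg.n_censuses + 1):
        dies = alive & (rng.random(n) < p_die)
        death_census[dies] = t
        alive &= ~dies
        day = t * cfg.census_interval_days
        for i, sid in enumerate(cov["seedling_id"]):
            surv_rows.append((sid, t, day, 0 if death_census[i] > t else 1))
    survival = pd.DataFrame(surv_rows,
                            columns=["seedling_id", "census", "day", "status"])

    stat_g = cov[cfg.growth_stat].to_numpy()
    mu = (cfg.growth_intercept + cfg.growth_beta_stat * stat_g
          + cfg.growth_beta_r * cov["r"].to_numpy()
          + cfg.growth_beta_w * cov["w"].to_numpy())
    u_i = rng.normal(0.0, cfg.growth_tau, size=n)
    death_day = death_census * cfg.census_interval_days
    h_rows = []
    H = np.exp(rng.normal(cfg.height0_logmean, cfg.height0_logsd, size=n))
    days = cfg.height_days
    for i, sid in enumerate(cov["seedling_id"]):
        if death_day[i] <= days[0]:
            continue
        h_rows.append((sid, days[0], H[i]))
    H_prev = H.copy()
    for p in range(1, len(days)):
        dt = days[p] - days[p - 1]
        rgr = mu + u_i + rng.normal(0.0, cfg.growth_sigma, size=n)
        H_curr = H_prev * np.exp(rgr * dt)
        for i, sid in enumerate(cov["seedling_id"]):
            if death_day[i] <= days[p]:
                continue
            h_rows.append((sid, days[p], H_curr[i]))
        H_prev = H_curr
    heights = pd.DataFrame(h_rows, columns=["seedling_id", "day", "height_cm"])
    heights = heights.sort_values(["seedling_id", "day"], kind="stable",
                                  ignore_index=True)

    seedlings_df = cov[["seedling_id", "mother_id", "w"]].rename(
        columns={"w": "seed_weight"})
    phen = PhenotypeTable(seedlings=seedlings_df, survival=survival,
                          heights=heights)
    return phen, truth


def simulate_all(cfg: SimConfig):
    """Run the three simulation stages off a single seeded generator."""
    rng = np.random.default_rng(cfg.rng_seed)
    adults, truth = simulate_adults(cfg, rng)
    seedlings, truth = simulate_matings(adults, truth, cfg, rng)
    phen, truth = simulate_fitness(seedlings, truth, cfg, rng)
    return adults, seedlings, phen, truth
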