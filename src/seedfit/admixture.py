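"""Bayesian admixture clustering with correlated allele frequencies.

Implements the F-model: every cluster's allele frequencies P_k drift from a
shared ancestral frequency vector P_A, with per-cluster drift parameter F_k
acting as that cluster's Fst from the ancestral admixed population
(P_k | P_A, F_k ~ Dirichlet(P_A * (1-F_k)/F_k)).  Each individual carries an
ancestry vector Q_i on the K-simplex (Q_i ~ Dirichlet(alpha)), and each
allele copy independently picks a cluster of origin Z from Q_i and then an
allele from P_Z.

Inference is by MCMC: Gibbs updates for the latent origins Z, the cluster
frequencies P and the ancestry vectors Q (all conjugate), and random-walk
Metropolis updates for P_A, F_k and alpha.  Model choice across K uses the
harmonic-approximation estimator L(K) = mean(lnL) - var(lnL)/2 of the log
model evidence and the Evanno ΔK second-difference statistic; replicate runs
are label-aligned by a greedy column matching.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy.special import gammaln

from .io import GenotypeTable, MISSING

logger = logging.getLogger("seedfit")

# Sampler step sizes / priors (mirroring common defaults for this model)
F_PRIOR_MEAN = 0.01
F_PRIOR_SD = 0.05
F_STEP_SD = 0.02
ALPHA_STEP_SD = 0.025
ALPHA_MAX = 10.0
PA_STEP_SD = 0.05
LAMBDA = 1.0          # ancestral-frequency Dirichlet parameter
THIN = 10             # record every THIN-th sweep


@dataclasses.dataclass
class AdmixtureFit:
    """Posterior summary of one MCMC run at a fixed K."""

    k: int
    ids: list
    loci: list
    q: np.ndarray              # (n, K) posterior mean ancestry
    p: np.ndarray              # (K, L, A) posterior mean cluster frequencies
    f: np.ndarray              # (K,) posterior mean drift (cluster Fst)
    alpha: float
    loglik_trace: np.ndarray   # recorded post-burn-in log-likelihoods
    allele_codes: list         # per locus, the codes indexing axis A
    warnings: list

    def q_frame(self):
        import pandas as pd
        return pd.DataFrame(self.q, index=self.ids,
                            columns=[f"Q{k+1}" for k in range(self.k)])


@dataclasses.dataclass
class RunSet:
    """Replicated fits over a contiguous range of K values."""

    fits: dict  # K -> list[AdmixtureFit]

    def k_values(self) -> list:
        return sorted(self.fits)

    def __post_init__(self):
        ks = self.k_values()
        if ks and ks != list(range(ks[0], ks[-1] + 1)):
            raise ValueError("K range must be contiguous")


def _prepare(g: GenotypeTable):
    """Map allele codes to dense per-locus indices; -1 marks missing copies."""
    n, L = g.n, g.n_loci
    codes_per_locus, a_idx = [], np.full((n, L, 2), -1, dtype=np.int64)
    for l in range(L):
        col = g.alleles[:, l, :]
        codes = sorted(int(c) for c in np.unique(col) if c != MISSING)
        codes_per_locus.append(codes)
        lut = {c: i for i, c in enumerate(codes)}
        for s in range(2):
            a_idx[:, l, s] = [lut.get(int(v), -1) for v in col[:, s]]
    A = max(len(c) for c in codes_per_locus)
    allele_mask = np.zeros((L, A), dtype=bool)
    for l, codes in enumerate(codes_per_locus):
        allele_mask[l, :len(codes)] = True
    return a_idx, allele_mask, codes_per_locus


def _sample_dirichlet(rng, shape_arr, mask):
    """Row-normalised gamma draws; entries outside ``mask`` stay 0."""
    gam = rng.gamma(np.maximum(shape_arr, 1e-9))
    gam = np.where(mask, np.maximum(gam, 1e-300), 0.0)
    return gam / gam.sum(axis=-1, keepdims=True)


def fit_admixture(g: GenotypeTable, k: int, burnin: int = 50_000,
                  iters: int = 150_000, seed=None, thin: int = THIN,
                  f_init: float = 0.05) -> AdmixtureFit:
    """Run the MCMC sampler and return posterior means.

    ``iters`` counts total sweeps including the first ``burnin``; states are
    recorded every ``thin`` sweeps after burn-in, so the log-likelihood trace
    has ``(iters - burnin) // thin`` entries.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    rng = np.random.default_rng(seed)
    n, L = g.n, g.n_loci
    a_idx, allele_mask, codes_per_locus = _prepare(g)
    A = allele_mask.shape[1]
    warn_list = []
    if all(len(c) <= 1 for c in codes_per_locus) and k > 1:
        warn_list.append("all loci monomorphic: F_k unidentifiable")
        warnings.warn(warn_list[-1])

    copy_mask = a_idx[:, :, 0] >= 0          # (n, L); both-or-neither holds
    copy_mask2 = np.repeat(copy_mask[:, :, None], 2, axis=2)
    a_safe = np.maximum(a_idx, 0)
    l_idx = np.arange(L)

    # ---- initial state ----
    counts0 = np.zeros((L, A))
    for l in range(L):
        vals = a_idx[:, l, :][copy_mask2[:, l, :]]
        counts0[l] = np.bincount(vals, minlength=A)
    pa = (counts0 + LAMBDA) * allele_mask
    pa = pa / pa.sum(axis=1, keepdims=True)
    f = np.full(k, f_init)
    alpha = 1.0
    q = rng.dirichlet(np.ones(k), size=n)
    p = np.stack([_sample_dirichlet(rng, pa * 50.0, allele_mask)
                  for _ in range(k)])

    n_rec = (iters - burnin) // thin
    trace = np.empty(n_rec)
    q_acc = np.zeros((n, k))
    p_acc = np.zeros((k, L, A))
    f_acc = np.zeros(k)
    alpha_acc = 0.0
    alpha_trace = []
    rec = 0

    for sweep in range(iters):
        # -- Z | Q, P: one categorical draw per allele copy
        pt = p.transpose(1, 2, 0)                      # (L, A, K)
        pz = q[:, None, None, :] * pt[l_idx[None, :, None], a_safe]  # (n,L,2,K)
        tot = pz.sum(-1)
        u = rng.random((n, L, 2)) * tot
        z = np.minimum((u[..., None] > np.cumsum(pz, -1)).sum(-1), k - 1)

        # -- P | Z, P_A, F (Dirichlet-conjugate)
        flat = (z * L + l_idx[None, :, None]) * A + a_safe
        cnt = np.bincount(flat[copy_mask2], minlength=k * L * A) \
            .reshape(k, L, A).astype(float)
        ratio = ((1.0 - f) / f)[:, None, None]
        p = _sample_dirichlet(rng, pa[None] * ratio + cnt, allele_mask[None])

        # -- Q | Z (Dirichlet-conjugate)
        zi = np.bincount(
            (np.repeat(np.arange(n), 2 * L).reshape(n, L, 2) * k + z)[copy_mask2],
            minlength=n * k).reshape(n, k).astype(float)
        qg = np.maximum(rng.gamma(alpha + zi), 1e-300)
        q = qg / qg.sum(1, keepdims=True)

        # -- P_A | P, F: per-locus pairwise-transfer Metropolis
        logp = np.log(p, where=p > 0, out=np.full_like(p, -np.inf))
        for l in range(L):
            nal = len(codes_per_locus[l])
            if nal < 2:
                continue
            i1, i2 = rng.choice(nal, size=2, replace=False)
            d = rng.normal(0.0, PA_STEP_SD)
            new1, new2 = pa[l, i1] + d, pa[l, i2] - d
            if new1 <= 0 or new2 <= 0 or new1 >= 1 or new2 >= 1:
                continue
            r_l = ratio[:, 0, 0]
            delta = (gammaln(pa[l, i1] * r_l) + gammaln(pa[l, i2] * r_l)
                     - gammaln(new1 * r_l) - gammaln(new2 * r_l)
                     + (new1 - pa[l, i1]) * r_l * logp[:, l, i1]
                     + (new2 - pa[l, i2]) * r_l * logp[:, l, i2]).sum()
            if np.log(rng.random()) < delta:
                pa[l, i1], pa[l, i2] = new1, new2

        # -- F_k: random-walk Metropolis, truncated-normal prior on (0,1)
        for kk in range(k):
            f_new = f[kk] + rng.normal(0.0, F_STEP_SD)
            if not (0.0 < f_new < 1.0):
                continue
            r_old = (1.0 - f[kk]) / f[kk]
            r_new = (1.0 - f_new) / f_new
            am = allele_mask
            ll_old = (gammaln(r_old * pa.sum(1, where=am)).sum()
                      - gammaln(np.where(am, r_old * pa, 1.0)).sum()
                      + ((r_old * pa - 1.0) * logp[kk])[am].sum())
            ll_new = (gammaln(r_new * pa.sum(1, where=am)).sum()
                      - gammaln(np.where(am, r_new * pa, 1.0)).sum()
                      + ((r_new * pa - 1.0) * logp[kk])[am].sum())
            lprior = (-0.5 * ((f_new - F_PRIOR_MEAN) / F_PRIOR_SD) ** 2
                      + 0.5 * ((f[kk] - F_PRIOR_MEAN) / F_PRIOR_SD) ** 2)
            if np.log(rng.random()) < ll_new - ll_old + lprior:
                f[kk] = f_new

        # -- alpha: random-walk Metropolis, uniform(0, ALPHA_MAX) prior
        if k > 1:
            a_new = alpha + rng.normal(0.0, ALPHA_STEP_SD)
            if 0.0 < a_new < ALPHA_MAX:
                slq = np.log(q).sum()
                ll = (n * (gammaln(k * a_new) - k * gammaln(a_new))
                      + (a_new - 1.0) * slq
                      - n * (gammaln(k * alpha) - k * gammaln(alpha))
                      - (alpha - 1.0) * slq)
                if np.log(rng.random()) < ll:
                    alpha = a_new

        if sweep >= burnin and (sweep - burnin) % thin == 0 and rec < n_rec:
            trace[rec] = np.log(tot[copy_mask]).sum()
            q_acc += q
            p_acc += p
            f_acc += f
            alpha_acc += alpha
            alpha_trace.append(alpha)
            rec += 1

    if rec == 0:
        raise ValueError("no samples recorded; increase iters")
    alpha_trace = np.array(alpha_trace)
    if k > 1 and alpha_trace.std() > 1.0:
        warn_list.append(f"alpha did not stabilise (trace sd "
                         f"{alpha_trace.std():.2f})")
        warnings.warn(warn_list[-1])
    return AdmixtureFit(
        k=k, ids=list(g.ids), loci=list(g.loci),
        q=q_acc / rec, p=p_acc / rec, f=f_acc / rec,
        alpha=alpha_acc / rec, loglik_trace=trace[:rec],
        allele_codes=codes_per_locus, warnings=warn_list,
    )


def run_k_range(g: GenotypeTable, k_min: int = 1, k_max: int = 6,
                reps: int = 5, burnin: int = 50_000, iters: int = 150_000,
                seed=None, thin: int = THIN) -> RunSet:
    """Replicated fits over K = k_min..k_max with seeds spawned from ``seed``."""
    ss = np.random.SeedSequence(seed)
    fits = {}
    for k in range(k_min, k_max + 1):
        fits[k] = [fit_admixture(g, k, burnin=burnin, iters=iters,
                                 seed=child, thin=thin)
                   for child in ss.spawn(reps)]
        logger.info("admixture: K=%d done (%d replicates)", k, reps)
    return RunSet(fits=fits)


def mean_ln_prob(fit: AdmixtureFit) -> float:
    """Model-evidence estimate L(K) = mean(lnL) - var(lnL)/2 over the trace."""
    t = np.asarray(fit.loglik_trace, dtype=float)
    if t.size < 10:
        raise ValueError("log-likelihood trace shorter than 10 samples")
    return float(t.mean() - t.var(ddof=1) / 2.0)


def evanno_delta_k(runs: RunSet):
    """Evanno table: per K the mean/sd of L(K) and the ΔK statistic.

    ΔK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)); undefined
    (NaN) at the endpoints of the K range.
    """
    import pandas as pd

    ks = runs.k_values()
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values for ΔK")
    if any(len(runs.fits[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicates per K for ΔK")
    mean_l = {k: np.mean([mean_ln_prob(f) for f in runs.fits[k]]) for k in ks}
    sd_l = {k: np.std([mean_ln_prob(f) for f in runs.fits[k]], ddof=1)
            for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            dk = np.nan
        else:
            num = abs(mean_l[k + 1] - 2.0 * mean_l[k] + mean_l[k - 1])
            if sd_l[k] == 0.0:
                warnings.warn(f"sd(L({k})) is 0; ΔK reported as +inf")
                dk = np.inf
            else:
                dk = num / sd_l[k]
        rows.append((k, mean_l[k], sd_l[k], dk))
    return pd.DataFrame(rows, columns=["K", "mean_L", "sd_L", "delta_K"])


def best_k(runs: RunSet) -> int:
    """K with the largest ΔK (endpoints are never candidates)."""
    tab = evanno_delta_k(runs)
    interior = tab.dropna(subset=["delta_K"])
    return int(interior.loc[interior["delta_K"].idxmax(), "K"])


def _greedy_permutation(ref_q: np.ndarray, run_q: np.ndarray) -> np.ndarray:
    """perm[j] = reference column matched to run column j (greedy, max dot)."""
    k = ref_q.shape[1]
    score = ref_q.T @ run_q                     # (ref k, run k)
    perm = np.full(k, -1)
    used_ref, used_run = set(), set()
    for _ in range(k):
        best, arg = -np.inf, None
        for i in range(k):
            if i in used_ref:
                continue
            for j in range(k):
                if j in used_run:
                    continue
                if score[i, j] > best:          # strict: ties keep lowest index
                    best, arg = score[i, j], (i, j)
        i, j = arg
        perm[j] = i
        used_ref.add(i)
        used_run.add(j)
    return perm


def align_runs(runs: RunSet, reference: int = 0) -> RunSet:
    """Align replicate runs of one K to a reference by column permutation."""
    ks = runs.k_values()
    if len(ks) != 1:
        raise ValueError("align_runs expects a RunSet with a single K")
    k = ks[0]
    fits = runs.fits[k]
    ref = fits[reference]
    aligned = []
    for fit in fits:
        if fit.k != ref.k:
            raise ValueError("K mismatch across runs")
        if fit.ids != ref.ids:
            raise ValueError("individual order mismatch across runs")
        perm = _greedy_permutation(ref.q, fit.q)
        inv = np.argsort(perm)                  # new column order
        aligned.append(dataclasses.replace(
            fit, q=fit.q[:, inv].copy(), p=fit.p[inv].copy(),
            f=fit.f[inv].copy()))
    return RunSet(fits={k: aligned})


def align_to_truth(fit: AdmixtureFit, truth_q: np.ndarray) -> AdmixtureFit:
    """Permute a fit's columns to best match a known ancestry matrix."""
    perm = _greedy_permutation(np.asarray(truth_q, dtype=float), fit.q)
    inv = np.argsort(perm)
    return dataclasses.replace(fit, q=fit.q[:, inv].copy(),
                               p=fit.p[inv].copy(), f=fit.f[inv].copy())


def cluster_fst(fit: AdmixtureFit) -> np.ndarray:
    """Posterior-mean drift F_k per cluster, in the fit's Q column order."""
    return np.asarray(fit.f, dtype=float)


def plot_q_bars(fit: AdmixtureFit, path) -> None:
    """Stacked-bar ancestry plot of the (aligned) Q matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(np.argmax(fit.q, axis=1), kind="stable")
    qs = fit.q[order]
    fig, ax = plt.subplots(figsize=(10, 2.5))
    bottom = np.zeros(len(qs))
    for k in range(fit.k):
        ax.bar(np.arange(len(qs)), qs[:, k], bottom=bottom, width=1.0)
        bottom += qs[:, k]
    ax.set_xlim(-0.5, len(qs) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("Q")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
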