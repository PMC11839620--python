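"""Relative growth rates and a Bayesian linear mixed model per period.

Height censuses are differenced into per-period relative growth rates
RGR = ln(H_t / H_{t-1}) / (T_t - T_{t-1}) in day^-1.  For each period the
model is

    RGR_s = b0 + b_stat * stat_s + b_r * r_s + b_w * w_s + u_{g(s)} + eps_s

with eps ~ Normal(0, sigma^2) and a random intercept u ~ Normal(0, tau^2)
grouped by mother tree by default (a per-seedling intercept — one
observation per seedling per period — is available behind ``group="seedling"``
and relies on the proper inverse-gamma prior to stay identified).  Priors:
coefficients Normal(0, 10^2), sigma^2 and tau^2 InverseGamma(0.001, 0.001),
all conjugate, so sampling is plain Gibbs.  Convergence is summarised by the
split-chain potential scale reduction factor; an effect is called non-zero
when its 95% credible interval excludes zero.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger("seedfit")

BETA_PRIOR_VAR = 100.0
IG_SHAPE = 0.001
IG_RATE = 0.001


def compute_rgr(heights: pd.DataFrame) -> pd.DataFrame:
    """Per-period relative growth rates from a height-census table.

    ``heights`` has columns (seedling_id, day, height_cm).  Periods are the
    intervals between consecutive days of the global measurement schedule;
    a seedling contributes a record for a period only when measured at both
    endpoints (dead or skipped seedlings contribute nothing).
    """
    if (heights["height_cm"] <= 0).any():
        bad = heights.loc[heights["height_cm"] <= 0, "seedling_id"].unique()
        raise ValueError(f"non-positive heights for {list(bad)[:5]}")
    days = sorted(heights["day"].unique())
    if len(days) < 2:
        raise ValueError("need at least two measurement days")
    if any(b - a <= 0 for a, b in zip(days, days[1:])):
        raise ValueError("zero-length measurement interval")
    day_rank = {d: i for i, d in enumerate(days)}
    rows = []
    for sid, grp in heights.groupby("seedling_id", sort=True):
        grp = grp.sort_values("day")
        d = grp["day"].to_numpy()
        h = grp["height_cm"].to_numpy(dtype=float)
        for a in range(len(d) - 1):
            if day_rank[d[a + 1]] != day_rank[d[a]] + 1:
                continue          # a skipped census; not a single period
            dt = float(d[a + 1] - d[a])
            rows.append((sid, day_rank[d[a + 1]], h[a], h[a + 1],
                         d[a], d[a + 1], float(np.log(h[a + 1] / h[a]) / dt)))
    return pd.DataFrame(rows, columns=["seedling_id", "period", "h_prev",
                                       "h_curr", "t_prev", "t_curr", "rgr"])


def rhat(chains) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` is (n_chains, n_draws) with >= 2 chains of equal length >= 10.
    Each chain is split in half; R = sqrt(((n-1)/n * W + B/n) / W) with W the
    mean within-half variance and B the between-half-mean variance times n.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 10:
        raise ValueError("need >= 2 chains of equal length >= 10")
    n_half = c.shape[1] // 2
    halves = np.concatenate([c[:, :n_half], c[:, n_half:2 * n_half]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    b = n_half * halves.mean(axis=1).var(ddof=1)
    if w == 0.0:
        if b > 0.0:
            return np.inf        # frozen chains at different values: no mixing
        warnings.warn("zero within- and between-chain variance; Rhat = 1.0")
        return 1.0
    return float(np.sqrt(((n_half - 1) / n_half * w + b / n_half) / w))


def fit_growth_model(records: pd.DataFrame, covariates: pd.DataFrame,
                     statistic: str = "qdis", chains: int = 3,
                     iters: int = 150_000, burnin: int = 30_000,
                     seed=None, group: str = "mother") -> pd.DataFrame:
    """Gibbs-sample the per-period growth model and summarise the posterior.

    ``records`` is one period's slice of :func:`compute_rgr` output;
    ``covariates`` carries (seedling_id, mother_id, w, r, qdis/fdis).
    ``iters`` counts total sweeps per chain including ``burnin``.  Returns a
    DataFrame indexed by parameter (intercept, statistic, r, w, sigma, tau)
    with columns mean, sd, 2.5%, 97.5%, Rhat, plus a ``warnings`` attribute
    listing convergence complaints (any Rhat > 1.1).
    """
    if chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    df = records.merge(covariates, on="seedling_id", how="inner")
    if df.empty:
        raise ValueError("no records after joining covariates")
    y = df["rgr"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), df[statistic], df["r"], df["w"]])
    names = ["intercept", statistic, "r", "w"]
    group_col = "mother_id" if group == "mother" else "seedling_id"
    codes, _ = pd.factorize(df[group_col])
    n_g = codes.max() + 1
    single_group = n_g < 2
    if single_group:
        warnings.warn("single grouping level; tau fixed at 0")
    n, p = X.shape
    xtx = X.T @ X
    rng = np.random.default_rng(seed)

    n_keep = iters - burnin
    draws = np.empty((chains, n_keep, p + 2))
    bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_var = max(np.var(y - X @ bhat), 1e-12)
    for ch in range(chains):
        beta = bhat + rng.normal(0, np.sqrt(resid_var), size=p)
        sigma2 = resid_var * rng.uniform(0.5, 2.0)
        tau2 = resid_var * rng.uniform(0.05, 0.5)
        u = np.zeros(n_g)
        for it in range(iters):
            # beta | rest
            prec = xtx / sigma2 + np.eye(p) / BETA_PRIOR_VAR
            r_vec = X.T @ (y - u[codes]) / sigma2
            cho = np.linalg.cholesky(np.linalg.inv(prec))
            beta = np.linalg.solve(prec, r_vec) + cho @ rng.normal(size=p)
            resid = y - X @ beta
            # u | rest
            if not single_group:
                sums = np.bincount(codes, weights=resid, minlength=n_g)
                cnts = np.bincount(codes, minlength=n_g)
                var_u = 1.0 / (cnts / sigma2 + 1.0 / tau2)
                u = (var_u * sums / sigma2
                     + np.sqrt(var_u) * rng.normal(size=n_g))
                # sum-to-zero recentring: the grand mean of u is exchanged
                # with the intercept, which breaks their joint flat direction
                shift = u.mean()
                u -= shift
                beta[0] += shift
                resid = y - X @ beta
                # tau^2 | u
                tau2 = 1.0 / rng.gamma(IG_SHAPE + n_g / 2.0,
                                       1.0 / (IG_RATE + 0.5 * (u ** 2).sum()))
            # sigma^2 | rest
            e = resid - u[codes]
            sigma2 = 1.0 / rng.gamma(IG_SHAPE + n / 2.0,
                                     1.0 / (IG_RATE + 0.5 * (e ** 2).sum()))
            if it >= burnin:
                k = it - burnin
                draws[ch, k, :p] = beta
                draws[ch, k, p] = np.sqrt(sigma2)
                draws[ch, k, p + 1] = 0.0 if single_group else np.sqrt(tau2)

    rows, warns = [], []
    all_names = names + ["sigma", "tau"]
    for j, name in enumerate(all_names):
        d = draws[:, :, j]
        r_j = 1.0 if (name == "tau" and single_group) else rhat(d)
        if r_j > 1.1:
            warns.append(f"Rhat({name}) = {r_j:.3f} > 1.1")
        flat = d.ravel()
        rows.append((name, flat.mean(), flat.std(ddof=1),
                     np.quantile(flat, 0.025), np.quantile(flat, 0.975), r_j))
    out = pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                      "2.5%", "97.5%", "Rhat"])
    out = out.set_index("parameter")
    if warns:
        warnings.warn("; ".join(warns))
    out.attrs["warnings"] = warns
    return out


def fit_growth_by_period(rgr: pd.DataFrame, covariates: pd.DataFrame,
                         statistic: str = "qdis", seed=None,
                         **kwargs) -> pd.DataFrame:
    """Fit the growth model separately for every period; stack summaries."""
    ss = np.random.SeedSequence(seed)
    out = []
    periods = sorted(rgr["period"].unique())
    for period, child in zip(periods, ss.spawn(len(periods))):
        summ = fit_growth_model(rgr[rgr["period"] == period], covariates,
                                statistic=statistic, seed=child, **kwargs)
        summ = summ.reset_index()
        summ.insert(0, "period", period)
        out.append(summ)
    return pd.concat(out, ignore_index=True)
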