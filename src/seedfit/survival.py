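"""Seedling survival coding and Cox proportional-hazards model comparison.

Census tables are coded to (time, event) records: the event time is the
first census at which a seedling is recorded dead (later records are
ignored), seedlings alive at the last census are right-censored.  The Cox
model is fitted by Newton–Raphson on the partial likelihood with Efron
(default) or Breslow handling of tied event times; standard errors come from
the inverse observed information.  Candidate models combine seed weight w,
parental relatedness r and one of the ancestry statistics qdis / fdis (never
both in one model), and are compared by AIC, BIC (sample size = number of
events) and deviance.  Kaplan–Meier curves grouped by qdis or fdis
thresholds go through lifelines.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger("seedfit")

ALLOWED_COVARIATES = ("w", "r", "qdis", "fdis")
DEFAULT_CUTS = {"qdis": (0.1, 0.35), "fdis": (0.02, 0.035)}

#: the standard model set: every covariate combination with at most one of
#: qdis/fdis (11 non-null models)
MODEL_SET = (
    ("w",), ("r",), ("fdis",), ("qdis",),
    ("w", "r"), ("w", "fdis"), ("w", "qdis"),
    ("r", "fdis"), ("r", "qdis"),
    ("w", "r", "fdis"), ("w", "r", "qdis"),
)


def code_survival(phenotypes) -> pd.DataFrame:
    """Code census statuses into one (time, event) record per seedling.

    ``time`` is the census index of first recorded death (event = 1) or the
    last census (event = 0).  A dead-then-alive sequence is an error.
    """
    rows = []
    for sid, grp in phenotypes.survival.groupby("seedling_id", sort=True):
        grp = grp.sort_values("census")
        status = grp["status"].to_numpy()
        dead = np.nonzero(status == 1)[0]
        if dead.size:
            if (status[dead[0]:] == 0).any():
                raise ValueError(f"seedling {sid}: recorded alive after death")
            rows.append((sid, int(grp["census"].iloc[dead[0]]), 1))
        else:
            rows.append((sid, int(grp["census"].iloc[-1]), 0))
    return pd.DataFrame(rows, columns=["seedling_id", "time", "event"])


@dataclasses.dataclass
class CoxFit:
    """A fitted proportional-hazards model."""

    covariates: tuple
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    log_partial_lik: float
    aic: float
    bic: float
    deviance: float
    df: int
    n: int
    n_events: int
    ties: str
    record_key: int    # fingerprint of the (id, time, event) records

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.coef, "se": self.se, "z": self.z,
                             "p": self.p}, index=list(self.covariates))


def _pl_grad_hess(beta, X, time, event, ties):
    """Log partial likelihood, gradient and Hessian (Efron or Breslow)."""
    p = X.shape[1]
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for t in np.unique(time[event == 1]):
        D = (time == t) & (event == 1)
        R = time >= t
        d = int(D.sum())
        wR = w[R]
        XR = X[R]
        sw_R = wR.sum()
        sx_R = XR.T @ wR
        sxx_R = XR.T @ (wR[:, None] * XR)
        wD = w[D]
        XD = X[D]
        sw_D = wD.sum()
        sx_D = XD.T @ wD
        sxx_D = XD.T @ (wD[:, None] * XD)
        ll += eta[D].sum()
        grad += XD.sum(axis=0)
        for l in range(d):
            phi = l / d if ties == "efron" else 0.0
            denom = sw_R - phi * sw_D
            xb = sx_R - phi * sx_D
            xxb = sxx_R - phi * sxx_D
            ll -= np.log(denom)
            grad -= xb / denom
            hess -= xxb / denom - np.outer(xb, xb) / denom ** 2
    return ll, grad, hess


def fit_cox(records: pd.DataFrame, covariates: pd.DataFrame, formula,
            ties: str = "efron", max_iter: int = 50,
            tol: float = 1e-9) -> CoxFit:
    """Fit a Cox model of the chosen covariate subset on coded records.

    ``records`` holds (seedling_id, time, event); ``covariates`` holds the
    per-seedling columns.  ``formula`` is an iterable of covariate names; it
    may contain at most one of qdis/fdis (the two statistics are alternative
    parameterisations of the same contrast and are analysed separately).
    """
    formula = tuple(formula)
    unknown = set(formula) - set(ALLOWED_COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariates {sorted(unknown)}")
    if "qdis" in formula and "fdis" in formula:
        raise ValueError("qdis and fdis are analysed separately; "
                         "a model may contain only one of them")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    df = records.merge(covariates, on="seedling_id", how="inner")
    if len(df) < len(records):
        logger.warning("fit_cox: %d records had no covariates and were dropped",
                       len(records) - len(df))
    df = df.sort_values("seedling_id", kind="stable")
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("no events in the records; cannot fit")
    X = df[list(formula)].to_numpy(dtype=float) if formula \
        else np.empty((len(df), 0))
    if formula and not np.isfinite(X).all():
        raise ValueError("non-finite covariate values")
    key = hash(tuple(map(tuple, df[["seedling_id", "time", "event"]]
                         .itertuples(index=False))))

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _pl_grad_hess(beta, X, time, event, ties)
    it = 0
    while p and it < max_iter:
        if np.abs(grad).max() < tol:
            break
        step = np.linalg.solve(hess, grad)
        new = beta - step
        ll_new, g_new, h_new = _pl_grad_hess(new, X, time, event, ties)
        halve = 0
        while ll_new < ll - 1e-12 and halve < 30:
            new = (beta + new) / 2.0
            ll_new, g_new, h_new = _pl_grad_hess(new, X, time, event, ties)
            halve += 1
        beta, ll, grad, hess = new, ll_new, g_new, h_new
        if np.abs(beta).max() > 50:
            raise RuntimeError(
                "partial likelihood appears monotone (perfect separation); "
                "consider penalised estimation or dropping the covariate")
        it += 1
    if p and np.abs(grad).max() >= 1e-6:
        warnings.warn(f"Cox fit: gradient norm {np.abs(grad).max():.2e} "
                      "above 1e-6 after Newton iterations")
    if p:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.empty(0)
    z = beta / se if p else np.empty(0)
    pvals = 2 * norm.sf(np.abs(z)) if p else np.empty(0)
    deviance = -2.0 * ll
    return CoxFit(covariates=formula, coef=beta, se=se, z=z, p=pvals,
                  log_partial_lik=ll, aic=deviance + 2 * p,
                  bic=deviance + p * np.log(n_events), deviance=deviance,
                  df=p, n=len(df), n_events=n_events, ties=ties,
                  record_key=key)


def model_table(fits) -> pd.DataFrame:
    """Comparison table over fits of the same records; flags the AIC minimum."""
    fits = list(fits)
    keys = {f.record_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were computed on different record sets")
    all_covs = [c for c in ALLOWED_COVARIATES
                if any(c in f.covariates for f in fits)]
    rows = []
    best_aic = min(f.aic for f in fits)
    for i, f in enumerate(fits, start=1):
        row = {"model": i}
        for c in all_covs:
            if c in f.covariates:
                j = f.covariates.index(c)
                row[c] = f.coef[j]
                row[f"{c}_se"] = f.se[j]
                row[f"{c}_p"] = f.p[j]
            else:
                row[c] = np.nan
                row[f"{c}_se"] = np.nan
                row[f"{c}_p"] = np.nan
        row.update(df=f.df, AIC=f.aic, BIC=f.bic, deviance=f.deviance,
                   best=bool(f.aic == best_aic))
        rows.append(row)
    return pd.DataFrame(rows)


def fit_model_set(records, covariates, statistic: str = None,
                  ties: str = "efron", skip_divergent: bool = False):
    """Fit the null model plus the standard 11-model family (or the subset
    using one statistic) and return (fits, comparison table).

    ``skip_divergent`` drops models whose partial likelihood is monotone
    (possible on very small cohorts) instead of aborting.
    """
    models = [()]
    for m in MODEL_SET:
        if statistic and (("qdis" in m and statistic != "qdis")
                          or ("fdis" in m and statistic != "fdis")):
            continue
        models.append(m)
    fits = []
    for m in models:
        try:
            fits.append(fit_cox(records, covariates, m, ties=ties))
        except RuntimeError:
            if not skip_divergent:
                raise
            logger.warning("model %s diverged and was skipped", m)
    return fits, model_table(fits)


def km_by_group(records: pd.DataFrame, covariates: pd.DataFrame,
                statistic: str = "qdis", cuts=None) -> dict:
    """Kaplan–Meier curves for seedlings grouped by thresholds on a statistic.

    Default cuts are (0.1, 0.35) for qdis and (0.02, 0.035) for fdis, giving
    groups 1 (below), 2 (between) and 3 (above).  Returns a dict
    group-label -> DataFrame(time, survival); empty groups are omitted with
    a warning.
    """
    from lifelines import KaplanMeierFitter

    if cuts is None:
        cuts = DEFAULT_CUTS[statistic]
    cuts = tuple(cuts)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cuts must be strictly increasing")
    df = records.merge(covariates[["seedling_id", statistic]], on="seedling_id")
    edges = (-np.inf,) + cuts + (np.inf,)
    out = {}
    for gi in range(len(edges) - 1):
        sel = df[(df[statistic] > edges[gi]) & (df[statistic] <= edges[gi + 1])]
        label = str(gi + 1)
        if sel.empty:
            warnings.warn(f"group {label} ({statistic} in "
                          f"({edges[gi]}, {edges[gi+1]}]) is empty; omitted")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sel["time"], event_observed=sel["event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        out[label] = sf
    return out


def plot_km(curves: dict, path, statistic: str = "qdis") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, sf in sorted(curves.items()):
        ax.step(sf["time"], sf["survival"], where="post",
                label=f"group {label}")
    ax.set_xlabel("census")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title=statistic)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
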