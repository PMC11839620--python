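"""Bi-parental ancestry statistics and the seedling covariate table.

Two scalar statistics summarise the genetic heterogeneity of a parent pair
from their ancestry vectors Q (rows of the admixture Q matrix):

* ``qdis`` — Rogers' distance applied to the two ancestry vectors,
  ``sqrt(sum_k (Q_ik - Q_jk)^2 / 2)``; 0 for identical ancestry, 1 for pure
  membership in two different clusters.
* ``fdis`` — a drift-weighted sum of the pair's cluster memberships,
  ``sum_k (Q_ik + Q_jk) * fst_k / 2``, where ``fst_k`` is a *signed*
  per-cluster differentiation value.  With the field estimates
  (0.10552, 0.00044, -0.10342) the statistic is ~0 both for parents resembling
  the undifferentiated cluster 2 and for pure cluster-1 x cluster-3 pairs,
  whose opposite-signed contributions cancel.

``assemble_covariates`` joins these statistics with seed weight and pairwise
relatedness into the per-seedling table the survival and growth models use,
keeping only seedlings with a single identified in-plot pollen donor.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("seedfit")

#: signed per-cluster differentiation from the ancestral admixed population
#: (clusters 1..3), the default weight vector for fdis
DEFAULT_SIGNED_FST = (0.10552, 0.00044, -0.10342)


def _check_simplex(q, name: str, tol: float = 1e-6) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.ndim != 1:
        raise ValueError(f"{name} must be a 1-D ancestry vector")
    if abs(q.sum() - 1.0) > tol or (q < -tol).any():
        raise ValueError(f"{name} is not on the probability simplex: {q}")
    return q


def qdis(q_i, q_j, squared: bool = False) -> float:
    """Rogers' distance between two ancestry vectors.

    ``squared=True`` returns the no-square-root reading
    ``sum_k (Q_ik - Q_jk)^2 / 2`` for sensitivity analysis.
    """
    q_i = _check_simplex(q_i, "q_i")
    q_j = _check_simplex(q_j, "q_j")
    if q_i.shape != q_j.shape:
        raise ValueError("ancestry vectors have different lengths")
    d2 = float(np.square(q_i - q_j).sum() / 2.0)
    return d2 if squared else float(np.sqrt(d2))


def fdis(q_i, q_j, fst) -> float:
    """Signed-drift-weighted mean of a pair's summed cluster memberships."""
    q_i = np.asarray(q_i, dtype=float)
    q_j = np.asarray(q_j, dtype=float)
    fst = np.asarray(fst, dtype=float)
    if not (q_i.shape == q_j.shape == fst.shape):
        raise ValueError("q_i, q_j and fst must have the same length")
    if not np.isfinite(fst).all():
        raise ValueError("fst vector must be finite")
    return float(((q_i + q_j) * fst).sum() / 2.0)


def signed_fst_contrast(f: np.ndarray, opposing_cluster: int = None) -> np.ndarray:
    """Map estimated drift values F_k in (0,1) to a signed fdis weight vector.

    The admixture model can only yield positive per-cluster drift; the fdis
    construction needs one cluster to act as the opposing pole.  By default
    the last of the two most-differentiated clusters is negated.
    """
    f = np.asarray(f, dtype=float).copy()
    if opposing_cluster is None:
        top2 = np.argsort(f)[-2:]
        opposing_cluster = int(max(top2))
    f[opposing_cluster] = -f[opposing_cluster]
    return f


def assemble_covariates(parentage: pd.DataFrame, q_table: pd.DataFrame,
                        fst, relatedness: pd.DataFrame,
                        phenotypes) -> pd.DataFrame:
    """Build the per-seedling covariate table (w, r, qdis, fdis).

    Parameters
    ----------
    parentage : DataFrame with seedling_id, mother_id, best_father_id, category
    q_table : DataFrame indexed by individual id with columns Q1..QK
    fst : signed per-cluster differentiation vector (length K)
    relatedness : DataFrame with id_i, id_j, r (mother-father pairs)
    phenotypes : PhenotypeTable (seed weights)

    Only ``single_donor`` records are kept; counts of the excluded categories
    are logged.  A single-donor record whose father has no ancestry vector is
    an error.
    """
    fst = np.asarray(fst, dtype=float)
    counts = parentage["category"].value_counts().to_dict()
    excluded = {c: counts.get(c, 0)
                for c in ("selfing", "immigrant", "ambiguous_multiple")}
    logger.info("covariate assembly: excluded %s", excluded)
    keep = parentage[parentage["category"] == "single_donor"]

    missing_q = [f for f in keep["best_father_id"]
                 if f not in q_table.index]
    missing_q += [m for m in keep["mother_id"].unique()
                  if m not in q_table.index]
    if missing_q:
        raise KeyError(f"no ancestry vector for: {sorted(set(missing_q))}")

    rel = {}
    if relatedness is not None and len(relatedness):
        for i, j, r in relatedness[["id_i", "id_j", "r"]].itertuples(index=False):
            rel[(i, j)] = r
            rel[(j, i)] = r
    weights = dict(zip(phenotypes.seedlings["seedling_id"],
                       phenotypes.seedlings["seed_weight"]))

    rows, dropped_w = [], 0
    for sid, mid, fid in keep[["seedling_id", "mother_id",
                               "best_father_id"]].itertuples(index=False):
        if sid not in weights or not np.isfinite(weights[sid]):
            dropped_w += 1
            continue
        qm = q_table.loc[mid].to_numpy(dtype=float)
        qf = q_table.loc[fid].to_numpy(dtype=float)
        rows.append((sid, mid, fid, float(weights[sid]),
                     float(rel.get((mid, fid), np.nan)),
                     qdis(qm, qf), fdis(qm, qf, fst)))
    if dropped_w:
        logger.warning("dropped %d seedlings with missing seed weight", dropped_w)
    return pd.DataFrame(rows, columns=["seedling_id", "mother_id", "father_id",
                                       "w", "r", "qdis", "fdis"])


def plot_histograms(covariates: pd.DataFrame, path) -> None:
    """Three-panel histogram of r, qdis and fdis across the cohort."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(10, 3))
    for ax, col in zip(axes, ("r", "qdis", "fdis")):
        ax.hist(covariates[col].dropna(), bins=25, color="steelblue")
        ax.set_xlabel(col)
    axes[0].set_ylabel("frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
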