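"""Maximum-likelihood pairwise relatedness from codominant markers.

A non-inbred pair's genotypes are governed by the IBD-sharing coefficients
(k0, k1, k2) — the probabilities of sharing 0, 1 or 2 alleles identical by
descent.  The per-locus likelihood is ``k0*S0 + k1*S1 + k2*S2`` where S_m is
the probability of the observed unordered genotype pair given m IBD alleles
(products of allele frequencies; S1/S2 vanish when the genotypes cannot share
the required alleles).  Relatedness is ``r = k1/2 + k2``.  The optimum over
the (k0, k1, k2) simplex is found by coarse grid search plus local
refinement, which is robust to boundary optima (true parent-offspring pairs
sit at k1 = 1, unrelated pairs at k0 = 1).
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .io import AlleleFreqTable

_JACQUARD_TOL = 1e-9


@dataclasses.dataclass
class PairRelatedness:
    id_i: str
    id_j: str
    k0: float
    k1: float
    k2: float
    r: float
    loglik: float


def _pair_s_terms(g_i, g_j, p) -> tuple:
    """(S0, S1, S2) for one locus given unordered genotypes and freq lookup.

    Standard no-inbreeding genotype-pair probabilities:
    S0 multiplies the two independent genotype probabilities; S1 conditions
    on one shared IBD allele; S2 requires identical genotypes.
    """
    a, b = sorted(g_i)
    c, d = sorted(g_j)
    pa, pb, pc, pd_ = p(a), p(b), p(c), p(d)
    prob_i = pa * pa if a == b else 2 * pa * pb
    prob_j = pc * pc if c == d else 2 * pc * pd_
    s0 = prob_i * prob_j
    # S2: identical unordered genotypes
    s2 = 0.0
    if (a, b) == (c, d):
        s2 = pa * pa if a == b else 2 * pa * pb
    # S1: one allele IBD between the pairs
    if a == b and c == d:
        s1 = pa ** 3 if a == c else 0.0
    elif a == b:                       # ii vs jk (j or k may equal i)
        if c == a:
            s1 = pa * pa * pd_
        elif d == a:
            s1 = pa * pa * pc
        else:
            s1 = 0.0
    elif c == d:                       # ij vs kk
        if a == c:
            s1 = pc * pc * pb
        elif b == c:
            s1 = pc * pc * pa
        else:
            s1 = 0.0
    else:                              # both heterozygous
        shared = {a, b} & {c, d}
        if {a, b} == {c, d}:
            s1 = pa * pb * (pa + pb)
        elif len(shared) == 1:
            s = shared.pop()
            other_i = b if a == s else a
            other_j = d if c == s else c
            s1 = p(s) * p(other_i) * p(other_j)
        else:
            s1 = 0.0
    return s0, s1, s2


def _shared_s_matrix(g_i, g_j, freqs: AlleleFreqTable) -> np.ndarray:
    """(L_shared, 3) matrix of S-terms over loci typed in both individuals."""
    rows = []
    for locus in freqs.loci:
        gi = g_i.get(locus)
        gj = g_j.get(locus)
        if gi is None or gj is None:
            continue
        rows.append(_pair_s_terms(gi, gj, lambda a, _l=locus: freqs.freq(_l, a)))
    if not rows:
        raise ValueError("no shared typed loci between the pair")
    return np.asarray(rows, dtype=float)


def pair_loglik(g_i, g_j, freqs: AlleleFreqTable, k) -> float:
    """Log-likelihood of IBD coefficients ``k = (k0, k1, k2)`` for one pair.

    ``g_i``/``g_j`` map locus -> unordered allele pair or None.
    """
    k = np.asarray(k, dtype=float)
    if k.shape != (3,) or (k < -_JACQUARD_TOL).any() \
            or abs(k.sum() - 1.0) > _JACQUARD_TOL:
        raise ValueError(f"invalid IBD coefficients {k}")
    s = _shared_s_matrix(g_i, g_j, freqs)
    lik = s @ k
    if (lik <= 0).any():
        return -np.inf
    return float(np.log(lik).sum())


def _k_grid(step: float) -> np.ndarray:
    k0 = np.arange(0.0, 1.0 + step / 2, step)
    grid = [(a, b, 1.0 - a - b) for a in k0 for b in k0 if a + b <= 1.0 + 1e-12]
    g = np.asarray(grid)
    g[:, 2] = np.maximum(g[:, 2], 0.0)
    return g / g.sum(axis=1, keepdims=True)


def _grid_loglik(s: np.ndarray, grid: np.ndarray) -> np.ndarray:
    lik = grid @ s.T                       # (G, L)
    with np.errstate(divide="ignore"):
        return np.where(lik > 0, np.log(lik), -np.inf).sum(axis=1)


def ml_relatedness(g_i, g_j, freqs: AlleleFreqTable, grid_step: float = 0.01,
                   ids=("i", "j"), constrain_pedigree: bool = False
                   ) -> PairRelatedness:
    """Maximise the pair likelihood over the IBD simplex.

    Coarse grid at ``grid_step`` followed by a 10x finer local grid around
    the best point.  ``constrain_pedigree`` restricts the search to
    coefficients satisfying k1^2 >= 4*k0*k2 (realisable by a pedigree without
    inbreeding).
    """
    s = _shared_s_matrix(g_i, g_j, freqs)
    grid = _k_grid(grid_step)
    if constrain_pedigree:
        grid = grid[grid[:, 1] ** 2 >= 4 * grid[:, 0] * grid[:, 2] - 1e-12]
    ll = _grid_loglik(s, grid)
    best = grid[int(np.argmax(ll))]
    # local refinement on a finer simplex patch
    fine = grid_step / 10.0
    lo0 = max(best[0] - grid_step, 0.0)
    lo1 = max(best[1] - grid_step, 0.0)
    pts = []
    for a in np.arange(lo0, min(best[0] + grid_step, 1.0) + fine / 2, fine):
        for b in np.arange(lo1, min(best[1] + grid_step, 1.0) + fine / 2, fine):
            if a + b <= 1.0 + 1e-12:
                pts.append((a, b, max(1.0 - a - b, 0.0)))
    local = np.asarray(pts)
    local = local / local.sum(axis=1, keepdims=True)
    if constrain_pedigree:
        keep = local[:, 1] ** 2 >= 4 * local[:, 0] * local[:, 2] - 1e-12
        if keep.any():
            local = local[keep]
    ll_local = _grid_loglik(s, local)
    j = int(np.argmax(ll_local))
    k0, k1, k2 = local[j]
    return PairRelatedness(id_i=ids[0], id_j=ids[1], k0=float(k0),
                           k1=float(k1), k2=float(k2),
                           r=float(k1 / 2 + k2), loglik=float(ll_local[j]))


def relatedness_for_pairs(g, pairs, freqs: AlleleFreqTable,
                          grid_step: float = 0.01):
    """ML relatedness for a list of (id_i, id_j) pairs from one table."""
    import pandas as pd

    cache = {}
    rows = []
    for i, j in pairs:
        key = (i, j) if i <= j else (j, i)
        if key not in cache:
            gi = {locus: g.genotype(key[0], locus) for locus in g.loci}
            gj = {locus: g.genotype(key[1], locus) for locus in g.loci}
            cache[key] = ml_relatedness(gi, gj, freqs, grid_step, ids=key)
        pr = cache[key]
        rows.append((i, j, pr.k0, pr.k1, pr.k2, pr.r, pr.loglik))
    return pd.DataFrame(rows, columns=["id_i", "id_j", "k0", "k1", "k2",
                                       "r", "loglik"])
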