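"""Likelihood-based paternity assignment with simulation-calibrated confidence.

For each offspring with a known mother, every plot adult (the mother
included, which is how selfing is detected) is scored with a LOD — the
summed log likelihood ratio, over shared typed loci, of "candidate is the
father" against "the father is a random male drawn from the allele
frequencies".  Genotyping error enters through a per-genotype mistyping rate
``e``: with probability ``e`` an observed offspring genotype is an unrelated
Hardy–Weinberg draw, so Mendelian incompatibilities are penalised but not
infinitely (at ``e = 0`` one incompatible locus drives the LOD to −inf).

The difference Δ between the top two candidates' LODs measures how clearly
the best candidate wins; its critical value is calibrated by simulating
offspring of known paternity and finding the smallest threshold at which at
least 95% of the assignments exceeding it are correct.  Assignment then
proceeds by ordered rules: selfing (mother wins and passes Δ), immigrant
(best candidate has more than ``max_mismatch`` Mendelian mismatches in the
simple exclusion procedure), ambiguous (Δ below critical), or single donor.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .io import AlleleFreqTable, GenotypeTable

logger = logging.getLogger("seedfit")

CATEGORIES = ("selfing", "immigrant", "ambiguous_multiple", "single_donor")


# ---------------------------------------------------------------------------
# Per-locus probability tables over the finite genotype space
# ---------------------------------------------------------------------------

class _LocusTables:
    """Transition/HW probabilities over all unordered genotypes at one locus."""

    MAX_ALLELES = 16   # the dense (G,G,G) table is O(na^6) in memory

    def __init__(self, codes, freqs):
        self.codes = list(codes)
        self.p = np.asarray(freqs, dtype=float)
        na = len(codes)
        if na > self.MAX_ALLELES:
            raise ValueError(
                f"{na} alleles at one locus exceeds the dense-table limit "
                f"({self.MAX_ALLELES}); bin rare alleles before assignment")
        pairs = [(i, j) for i in range(na) for j in range(i, na)]
        self.pair_index = {pr: g for g, pr in enumerate(pairs)}
        G = len(pairs)
        self.hw = np.empty(G)
        for (i, j), g in self.pair_index.items():
            self.hw[g] = self.p[i] ** 2 if i == j else 2 * self.p[i] * self.p[j]
        # T[go, gm, gf]: P(offspring genotype | parent pair), Mendelian
        self.T = np.zeros((G, G, G))
        for (m1, m2), gm in self.pair_index.items():
            for (f1, f2), gf in self.pair_index.items():
                for ma in (m1, m2):
                    for fa in (f1, f2):
                        go = self.pair_index[(min(ma, fa), max(ma, fa))]
                        self.T[go, gm, gf] += 0.25
        # PD[go, gm]: P(offspring | mother, random father from frequencies)
        self.PD = np.zeros((G, G))
        for (m1, m2), gm in self.pair_index.items():
            for ma in (m1, m2):
                for c in range(na):
                    go = self.pair_index[(min(ma, c), max(ma, c))]
                    self.PD[go, gm] += 0.5 * self.p[c]

    def geno_index(self, pair):
        i = self.codes.index(pair[0])
        j = self.codes.index(pair[1])
        return self.pair_index[(min(i, j), max(i, j))]


def _build_tables(freqs: AlleleFreqTable, *tables: GenotypeTable):
    """One ``_LocusTables`` per locus over the union of alleles seen anywhere."""
    loci = freqs.loci
    out = {}
    for l, locus in enumerate(loci):
        codes = set(freqs.freqs[locus])
        for g in tables:
            if g is None:
                continue
            col = g.alleles[:, g.loci.index(locus), :]
            codes.update(int(c) for c in np.unique(col) if c != 0)
        codes = sorted(codes)
        p = np.array([freqs.freq(locus, c) for c in codes])
        if (p <= 0).any():
            # unsmoothed frequencies: unseen alleles get probability 0 and act
            # as hard exclusions
            p = np.maximum(p, 0.0)
        out[locus] = _LocusTables(codes, p)
    return out


def _geno_dict(g: GenotypeTable, individual_id):
    return {locus: g.genotype(individual_id, locus) for locus in g.loci}


# ---------------------------------------------------------------------------
# Scalar operations (single trio)
# ---------------------------------------------------------------------------

def _trio_terms(offspring, mother, candidate, tables, error_rate):
    """Yield (num, den) likelihood terms per shared typed locus."""
    any_locus = False
    for locus, tab in tables.items():
        go_p = offspring.get(locus)
        gm_p = mother.get(locus)
        gf_p = candidate.get(locus)
        if go_p is None or gm_p is None or gf_p is None:
            continue
        any_locus = True
        go, gm, gf = (tab.geno_index(go_p), tab.geno_index(gm_p),
                      tab.geno_index(gf_p))
        e = error_rate
        num = (1 - e) * tab.T[go, gm, gf] + e * tab.hw[go]
        den = (1 - e) * tab.PD[go, gm] + e * tab.hw[go]
        yield num, den
    if not any_locus:
        raise ValueError("no shared typed loci between offspring, mother and candidate")


def lod_score(offspring, mother, candidate, freqs: AlleleFreqTable,
              error_rate: float = 0.0) -> float:
    """LOD of one candidate father for one offspring given the mother.

    ``offspring``/``mother``/``candidate`` are mappings locus -> unordered
    allele pair (or None for missing), as returned by
    ``GenotypeTable.genotype``.  Loci missing in any of the three are skipped.
    """
    tables = _build_tables_from_genos(freqs, offspring, mother, candidate)
    lod = 0.0
    for num, den in _trio_terms(offspring, mother, candidate, tables, error_rate):
        if num == 0.0:
            return -np.inf
        lod += np.log(num / den)
    return lod


def _build_tables_from_genos(freqs, *genos):
    loci = freqs.loci
    out = {}
    for locus in loci:
        codes = set(freqs.freqs[locus])
        for g in genos:
            pair = g.get(locus)
            if pair is not None:
                codes.update(pair)
        codes = sorted(codes)
        p = np.array([freqs.freq(locus, c) for c in codes])
        out[locus] = _LocusTables(codes, p)
    return out


def mismatch_count(offspring, mother, candidate,
                   freqs: AlleleFreqTable = None) -> int:
    """Loci at which no Mendelian maternal/paternal assignment exists."""
    if freqs is None:
        # frequencies are irrelevant for pure exclusion; build flat tables
        loci = set(offspring) | set(mother) | set(candidate)
        freqs = AlleleFreqTable(
            freqs={l: {} for l in sorted(loci)},
            n_typed={l: 0 for l in loci},
            unseen={l: 1.0 for l in loci})
    tables = _build_tables_from_genos(freqs, offspring, mother, candidate)
    count = 0
    for locus, tab in tables.items():
        go_p, gm_p, gf_p = (offspring.get(locus), mother.get(locus),
                            candidate.get(locus))
        if go_p is None or gm_p is None or gf_p is None:
            continue
        if tab.T[tab.geno_index(go_p), tab.geno_index(gm_p),
                 tab.geno_index(gf_p)] == 0.0:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Vectorised cohort machinery
# ---------------------------------------------------------------------------

def _geno_index_matrix(g: GenotypeTable, tables) -> np.ndarray:
    """(n, L) genotype indices into each locus table; -1 where missing."""
    n, L = g.n, g.n_loci
    out = np.full((n, L), -1, dtype=np.int64)
    for l, locus in enumerate(g.loci):
        tab = tables[locus]
        lut = {c: i for i, c in enumerate(tab.codes)}
        col = g.alleles[:, l, :]
        for i in range(n):
            a, b = col[i]
            if a == 0:
                continue
            ia, ib = lut[int(a)], lut[int(b)]
            out[i, l] = tab.pair_index[(min(ia, ib), max(ia, ib))]
    return out


def _locus_log_tables(tables, loci, error_rate):
    """Per locus: log-num (G,G,G), log-den (G,G) and mismatch mask (G,G,G)."""
    out = []
    e = error_rate
    for locus in loci:
        tab = tables[locus]
        num = (1 - e) * tab.T + e * tab.hw[:, None, None]
        den = (1 - e) * tab.PD + e * tab.hw[:, None]
        with np.errstate(divide="ignore"):
            out.append((np.log(num), np.log(den), tab.T == 0.0))
    return out


@dataclasses.dataclass
class ConfidenceCalibration:
    """Critical Δ for ≥95%-confident assignments, plus simulation settings."""

    delta_crit_95: float
    n_sim: int
    n_candidates: int
    sampled_fraction: float
    typed_fraction: float
    error_rate: float


def calibrate_delta(freqs: AlleleFreqTable, n_sim: int = 100_000,
                    n_candidates: int = 600, sampled_fraction: float = 1.0,
                    typed_fraction: float = 1.0, error_rate: float = 0.001,
                    seed=None, batch: int = 2000) -> ConfidenceCalibration:
    """Calibrate the 95% Δ threshold by simulating offspring of known paternity.

    Each simulated case draws a mother and ``n_candidates`` candidate fathers
    from Hardy–Weinberg at the supplied frequencies; the true father is among
    the candidates with probability ``sampled_fraction``.  The offspring is a
    Mendelian draw with per-locus mistyping at ``error_rate`` and each locus
    typed with probability ``typed_fraction``.  The returned threshold is the
    smallest Δ such that at least 95% of the cases whose Δ exceeds it have
    the true father as top candidate.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    rng = np.random.default_rng(seed)
    tables = _build_tables(freqs)
    loci = freqs.loci
    L = len(loci)
    logtabs = _locus_log_tables(tables, loci, error_rate)
    deltas = np.empty(n_sim)
    correct = np.zeros(n_sim, dtype=bool)
    done = 0
    while done < n_sim:
        b = min(batch, n_sim - done)
        lod = np.zeros((b, n_candidates))
        sampled = rng.random(b) < sampled_fraction
        for l, locus in enumerate(loci):
            tab = tables[locus]
            na = len(tab.codes)
            cdf = np.cumsum(tab.p)

            def draw(shape):
                return np.minimum((rng.random(shape)[..., None]
                                   > cdf).sum(-1), na - 1)

            mother = draw((b, 2))
            father = draw((b, 2))
            cand = draw((b, n_candidates, 2))
            # true father occupies column 0 when sampled
            cand[sampled, 0, :] = father[sampled]
            ma = mother[np.arange(b), rng.integers(2, size=b)]
            fa = father[np.arange(b), rng.integers(2, size=b)]
            off = np.stack([np.minimum(ma, fa), np.maximum(ma, fa)], axis=1)
            # per-genotype mistyping: replace with a random HW genotype
            err = rng.random(b) < error_rate
            if err.any():
                repl = draw((int(err.sum()), 2))
                off[err] = np.sort(repl, axis=1)
            typed = rng.random(b) < typed_fraction

            pair_lut = np.zeros((na, na), dtype=np.int64)
            for (i, j), gi in tab.pair_index.items():
                pair_lut[i, j] = pair_lut[j, i] = gi
            go = pair_lut[off[:, 0], off[:, 1]]
            gm = pair_lut[mother[:, 0], mother[:, 1]]
            gf = pair_lut[cand[..., 0], cand[..., 1]]
            lnum, lden, _ = logtabs[l]
            contrib = lnum[go[:, None], gm[:, None], gf] - lden[go, gm][:, None]
            lod[typed] += contrib[typed]
        top = np.argmax(lod, axis=1)
        part = np.partition(lod, -2, axis=1)
        deltas[done:done + b] = part[:, -1] - part[:, -2]
        correct[done:done + b] = (top == 0) & sampled
        done += b

    order = np.argsort(-deltas, kind="stable")
    acc = np.cumsum(correct[order]) / np.arange(1, n_sim + 1)
    ok = np.nonzero(acc >= 0.95)[0]
    if ok.size == 0:
        warnings.warn("95% confidence unattainable; delta_crit_95 = +inf")
        crit = np.inf
    else:
        i = ok.max()      # largest prefix still >= 95% correct
        crit = 0.0 if i == n_sim - 1 else float(deltas[order][i + 1])
        crit = max(crit, 0.0)
    return ConfidenceCalibration(
        delta_crit_95=crit, n_sim=n_sim, n_candidates=n_candidates,
        sampled_fraction=sampled_fraction, typed_fraction=typed_fraction,
        error_rate=error_rate)


def assign_paternity(seedlings: GenotypeTable, mothers, adults: GenotypeTable,
                     freqs: AlleleFreqTable, calib: ConfidenceCalibration,
                     error_rate: float = None,
                     max_mismatch: int = 2) -> pd.DataFrame:
    """Assign each seedling to a paternity category by the ordered rules.

    ``mothers`` maps seedling_id -> mother_id; every mother must be in
    ``adults`` (the candidate list).  Rules, in order: (1) the mother herself
    wins with Δ ≥ Δ_crit → selfing; (2) the best candidate exceeds
    ``max_mismatch`` Mendelian mismatches → immigrant; (3) Δ < Δ_crit →
    ambiguous_multiple; (4) otherwise single_donor.
    """
    if error_rate is None:
        error_rate = calib.error_rate
    if hasattr(mothers, "itertuples"):        # DataFrame(seedling_id, mother_id)
        mothers = dict(zip(mothers["seedling_id"], mothers["mother_id"]))
    unknown = [s for s in seedlings.ids if s not in mothers]
    if unknown:
        raise KeyError(f"seedlings with unknown mother: {unknown[:5]}...")
    bad_mother = sorted({m for m in mothers.values() if m not in adults.ids})
    if bad_mother:
        raise KeyError(f"mothers not in candidate list: {bad_mother}")

    tables = _build_tables(freqs, adults, seedlings)
    loci = freqs.loci
    logtabs = _locus_log_tables(tables, loci, error_rate)
    g_ad = _geno_index_matrix(adults, tables)
    g_se = _geno_index_matrix(seedlings, tables)
    adult_row = {iid: i for i, iid in enumerate(adults.ids)}
    n_cand = adults.n
    crit = calib.delta_crit_95

    records = []
    for s_i, sid in enumerate(seedlings.ids):
        m_row = adult_row[mothers[sid]]
        lod = np.zeros(n_cand)
        mm = np.zeros(n_cand, dtype=np.int64)
        shared = False
        for l in range(len(loci)):
            go, gm = g_se[s_i, l], g_ad[m_row, l]
            if go < 0 or gm < 0:
                continue
            gf = g_ad[:, l]
            ok = gf >= 0
            if not ok.any():
                continue
            shared = True
            lnum, lden, mmask = logtabs[l]
            contrib = lnum[go, gm, gf[ok]] - lden[go, gm]
            lod[ok] += contrib
            mm[ok] += mmask[go, gm, gf[ok]]
        if not shared:
            raise ValueError(f"seedling {sid}: no shared typed loci with candidates")
        order = np.argsort(-lod, kind="stable")
        best, second = order[0], order[1] if n_cand > 1 else None
        lod1 = float(lod[best])
        lod2 = float(lod[second]) if second is not None else -np.inf
        delta = lod1 - lod2
        if not np.isfinite(lod1) and not np.isfinite(lod2):
            delta = 0.0                          # all candidates excluded
        best_id = adults.ids[best]
        # a tied Δ (= 0) never supports an assignment, even when crit is 0
        passes = np.isfinite(lod1) and delta > 0.0 and delta >= crit
        if best_id == mothers[sid] and passes:
            category, father = "selfing", best_id
        elif mm[best] > max_mismatch:
            category, father = "immigrant", None
        elif not passes:
            category, father = "ambiguous_multiple", None
        else:
            category, father = "single_donor", best_id
        records.append((sid, mothers[sid], father, lod1, lod2, delta,
                        int(mm[best]), category))
    df = pd.DataFrame(records, columns=["seedling_id", "mother_id",
                                        "best_father_id", "lod1", "lod2",
                                        "delta", "mismatches", "category"])
    counts = df["category"].value_counts().to_dict()
    logger.info("paternity categories: %s (total %d)", counts, len(df))
    return df


def category_table(parentage: pd.DataFrame) -> pd.DataFrame:
    """Per-mother category bookkeeping (cohort accounting identity)."""
    tab = (parentage.groupby("mother_id")["category"]
           .value_counts().unstack(fill_value=0)
           .reindex(columns=list(CATEGORIES), fill_value=0))
    tab["total"] = tab.sum(axis=1)
    donors = (parentage[parentage["category"] == "single_donor"]
              .groupby("mother_id")["best_father_id"].nunique())
    tab["n_donors"] = donors.reindex(tab.index).fillna(0).astype(int)
    return tab.reset_index()
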