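"""Domain containers and file formats for codominant microsatellite data.

Genotypes are diploid, multi-locus and unphased: each individual carries an
unordered pair of allele codes per locus, where a code is an opaque positive
integer (typically a fragment size in base pairs).  Two on-disk dialects are
supported: classic GenePop (2- or 3-digit allele coding) and a "wide" CSV with
two columns per locus.  The module also estimates smoothed per-locus allele
frequencies, the shared input of every downstream likelihood.
"""
from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("seedfit")

#: allele code marking a missing slot inside the (n, n_loci, 2) array
MISSING = 0


class ParseError(ValueError):
    """Raised for malformed genotype files; message names the offending line."""


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenotypeTable:
    """Diploid genotypes for ``n`` individuals at ``n_loci`` loci.

    Parameters
    ----------
    ids : list of str
        Unique individual identifiers.
    groups : list of str
        Population / plot label per individual.
    loci : list of str
        Ordered locus names.
    alleles : ndarray of int, shape (n, n_loci, 2)
        Allele codes; ``0`` in both slots marks a missing locus.  A locus is
        either fully typed or fully missing for an individual.
    """

    ids: list
    groups: list
    loci: list
    alleles: np.ndarray

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n = len(self.ids)
        if self.alleles.shape != (n, len(self.loci), 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"{n} individuals x {len(self.loci)} loci x 2"
            )
        if len(self.groups) != n:
            raise ValueError("groups length does not match ids")
        if len(set(self.ids)) != n:
            raise ValueError("individual ids are not unique")
        if (self.alleles < 0).any():
            raise ValueError("allele codes must be positive integers (0 = missing)")
        self._coerce_half_missing()

    def _coerce_half_missing(self):
        """Force the both-or-neither rule: half-typed loci become missing."""
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            n_bad = int(half.sum())
            logger.warning(
                "%d half-missing locus record(s) coerced to fully missing", n_bad
            )
            self.alleles[half] = MISSING

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def index_of(self, individual_id) -> int:
        try:
            return self.ids.index(individual_id)
        except ValueError:
            raise KeyError(f"unknown individual id {individual_id!r}") from None

    def genotype(self, individual_id, locus):
        """Unordered allele pair ``(a, b)`` with ``a <= b``, or ``None`` if missing."""
        i = self.index_of(individual_id)
        l = self.loci.index(locus)
        a, b = self.alleles[i, l]
        if a == MISSING:
            return None
        return (int(min(a, b)), int(max(a, b)))

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, n_loci) mask, True where the locus is missing."""
        return self.alleles[:, :, 0] == MISSING

    def subset(self, ids) -> "GenotypeTable":
        idx = [self.index_of(i) for i in ids]
        return GenotypeTable(
            ids=[self.ids[i] for i in idx],
            groups=[self.groups[i] for i in idx],
            loci=list(self.loci),
            alleles=self.alleles[idx].copy(),
        )

    def concat(self, other: "GenotypeTable") -> "GenotypeTable":
        if self.loci != other.loci:
            raise ValueError("locus lists differ; cannot concatenate")
        return GenotypeTable(
            ids=self.ids + other.ids,
            groups=self.groups + other.groups,
            loci=list(self.loci),
            alleles=np.concatenate([self.alleles, other.alleles], axis=0),
        )

    def missing_report(self) -> pd.DataFrame:
        """Per-locus typed/missing counts (stands in for external QC tooling)."""
        miss = self.missing_mask().sum(axis=0)
        return pd.DataFrame(
            {
                "locus": self.loci,
                "n_typed": self.n - miss,
                "n_missing": miss,
                "missing_fraction": miss / self.n,
            }
        )


# ---------------------------------------------------------------------------
# GenePop reader / writer
# ---------------------------------------------------------------------------

def _parse_genepop_token(token: str, lineno: int):
    if len(token) == 4:
        w = 2
    elif len(token) == 6:
        w = 3
    else:
        raise ParseError(
            f"line {lineno}: genotype token {token!r} is not 2- or 3-digit coded"
        )
    try:
        a, b = int(token[:w]), int(token[w:])
    except ValueError:
        raise ParseError(f"line {lineno}: non-numeric genotype token {token!r}")
    return a, b


def read_genepop(path) -> GenotypeTable:
    """Read a GenePop file (2- or 3-digit allele coding; 0 = missing)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("line 1: file too short for GenePop format")
    # locus names: either comma-separated on line 2 or one per line until POP
    cursor = 1
    loci: list = []
    if "," in lines[1]:
        loci = [t.strip() for t in lines[1].split(",") if t.strip()]
        cursor = 2
    else:
        while cursor < len(lines) and lines[cursor].strip().lower() != "pop":
            name = lines[cursor].strip()
            if name:
                loci.append(name)
            cursor += 1
    if not loci:
        raise ParseError("line 2: no locus names found")
    ids, groups, rows = [], [], []
    pop_idx = 0
    for lineno0, raw in enumerate(lines[cursor:], start=cursor + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if pop_idx == 0:
            raise ParseError(f"line {lineno0}: expected 'POP' before individuals")
        if "," not in line:
            raise ParseError(f"line {lineno0}: missing ',' between id and genotypes")
        name, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"line {lineno0}: {len(tokens)} genotype tokens for {len(loci)} loci"
            )
        ids.append(name.strip())
        groups.append(f"pop{pop_idx}")
        rows.append([_parse_genepop_token(t, lineno0) for t in tokens])
    if not ids:
        raise ParseError("no individuals found after 'POP'")
    return GenotypeTable(ids=ids, groups=groups, loci=loci,
                         alleles=np.array(rows, dtype=np.int64))


def write_genepop(g: GenotypeTable, path, title: str = "seedfit export") -> None:
    """Write 3-digit GenePop; individuals grouped into POP blocks by label."""
    if (g.alleles > 999).any():
        raise ValueError("allele codes exceed 999; cannot use 3-digit GenePop coding")
    out = [title]
    out.extend(g.loci)
    last_group = None
    for i, (ind, grp) in enumerate(zip(g.ids, g.groups)):
        if grp != last_group:
            out.append("POP")
            last_group = grp
        toks = " ".join(f"{a:03d}{b:03d}" for a, b in g.alleles[i])
        out.append(f"{ind} , {toks}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Wide-CSV reader / writer
# ---------------------------------------------------------------------------

_NA_CODES = {"", "na", "nan", "-9", "0"}


def read_wide_csv(path) -> GenotypeTable:
    """Read the wide dialect: columns ``id, group, <locus>_1, <locus>_2, ...``."""
    df = pd.read_csv(path, dtype=str).fillna("")
    cols = list(df.columns)
    if len(cols) < 4 or cols[0] != "id" or cols[1] != "group":
        raise ParseError("wide CSV must start with columns 'id', 'group'")
    allele_cols = cols[2:]
    if len(allele_cols) % 2 != 0:
        raise ParseError(f"odd number of allele columns ({len(allele_cols)})")
    loci = []
    for j in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[j], allele_cols[j + 1]
        m1 = re.fullmatch(r"(.+)_1", c1)
        m2 = re.fullmatch(r"(.+)_2", c2)
        if not (m1 and m2 and m1.group(1) == m2.group(1)):
            raise ParseError(f"columns {c1!r}, {c2!r} are not a <locus>_1/_2 pair")
        loci.append(m1.group(1))

    def code(v: str) -> int:
        v = v.strip()
        if v.lower() in _NA_CODES:
            return MISSING
        try:
            iv = int(float(v))
        except ValueError:
            raise ParseError(f"non-numeric allele value {v!r}")
        return MISSING if iv <= 0 else iv

    n = len(df)
    alleles = np.zeros((n, len(loci), 2), dtype=np.int64)
    for l in range(len(loci)):
        alleles[:, l, 0] = [code(v) for v in df.iloc[:, 2 + 2 * l]]
        alleles[:, l, 1] = [code(v) for v in df.iloc[:, 3 + 2 * l]]
    return GenotypeTable(ids=df["id"].tolist(), groups=df["group"].tolist(),
                         loci=loci, alleles=alleles)


def write_wide_csv(g: GenotypeTable, path) -> None:
    data = {"id": g.ids, "group": g.groups}
    for l, locus in enumerate(g.loci):
        data[f"{locus}_1"] = g.alleles[:, l, 0]
        data[f"{locus}_2"] = g.alleles[:, l, 1]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AlleleFreqTable:
    """Smoothed per-locus allele frequencies.

    ``freqs[locus][allele]`` sums to 1 per locus.  ``unseen[locus]`` is the
    frequency assigned to an allele never observed at that locus (what one
    extra pseudo-observation would receive); it is 0 when smoothing is 0, in
    which case an unseen allele contributes ``log 0`` to any likelihood --
    i.e. behaves as a hard exclusion.
    """

    freqs: dict
    n_typed: dict
    unseen: dict

    @property
    def loci(self) -> list:
        return list(self.freqs)

    def freq(self, locus, allele) -> float:
        return self.freqs[locus].get(int(allele), self.unseen[locus])

    def alleles(self, locus) -> list:
        return sorted(self.freqs[locus])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (locus, a, f, self.n_typed[locus])
            for locus, fr in self.freqs.items()
            for a, f in sorted(fr.items())
        ]
        return pd.DataFrame(rows, columns=["locus", "allele", "freq", "n"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AlleleFreqTable":
        df = pd.read_csv(path)
        freqs, n_typed = {}, {}
        for locus, grp in df.groupby("locus", sort=False):
            freqs[locus] = dict(zip(grp["allele"].astype(int), grp["freq"]))
            n_typed[locus] = int(grp["n"].iloc[0])
        unseen = {locus: 0.0 for locus in freqs}
        return cls(freqs=freqs, n_typed=n_typed, unseen=unseen)


def allele_frequencies(g: GenotypeTable, smoothing: float = 0.5) -> AlleleFreqTable:
    """Estimate allele frequencies per locus with pseudo-count smoothing.

    Each allele observed at a locus gets ``smoothing`` added to its gene-copy
    count before renormalisation, so no observed allele ever has frequency 0
    (avoiding −inf log-likelihoods for alleles seen only in offspring).
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    freqs, n_typed, unseen = {}, {}, {}
    empty = [loc for l, loc in enumerate(g.loci)
             if (g.alleles[:, l, 0] == MISSING).all()]
    if empty:
        raise ValueError(f"loci with zero typed individuals: {empty}")
    for l, locus in enumerate(g.loci):
        col = g.alleles[:, l, :]
        typed = col[col[:, 0] != MISSING]
        codes, counts = np.unique(typed.ravel(), return_counts=True)
        total = counts.sum() + smoothing * len(codes)
        freqs[locus] = {int(c): (cnt + smoothing) / total
                        for c, cnt in zip(codes, counts)}
        n_typed[locus] = len(typed)
        # the share one extra pseudo-observed allele would take
        unseen[locus] = smoothing / (counts.sum() + smoothing * (len(codes) + 1))
    return AlleleFreqTable(freqs=freqs, n_typed=n_typed, unseen=unseen)


# ---------------------------------------------------------------------------
# Phenotypes: seed weight, survival censuses, height censuses
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PhenotypeTable:
    """Seedling phenotypes: seed weight plus survival and height censuses.

    seedlings : DataFrame(seedling_id, mother_id, seed_weight)
    survival  : DataFrame(seedling_id, census, day, status) with status 0 =
                alive, 1 = dead; census indices strictly increasing.
    heights   : DataFrame(seedling_id, day, height_cm); days strictly
                increasing per seedling.
    """

    seedlings: pd.DataFrame
    survival: pd.DataFrame
    heights: pd.DataFrame

    def __post_init__(self):
        if (self.seedlings["seed_weight"] <= 0).any():
            bad = self.seedlings.loc[self.seedlings["seed_weight"] <= 0, "seedling_id"]
            raise ValueError(f"non-positive seed weight for {list(bad)}")
        for name, df, col in (("survival", self.survival, "census"),
                              ("heights", self.heights, "day")):
            if len(df) and (df.groupby("seedling_id")[col].diff().dropna() <= 0).any():
                raise ValueError(f"{name}: {col} values not strictly increasing")

    def write_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.seedlings.to_csv(outdir / "seedlings.csv", index=False)
        self.survival.to_csv(outdir / "survival.csv", index=False)
        self.heights.to_csv(outdir / "heights.csv", index=False)

    @classmethod
    def read_dir(cls, outdir) -> "PhenotypeTable":
        outdir = Path(outdir)
        return cls(
            seedlings=pd.read_csv(outdir / "seedlings.csv"),
            survival=pd.read_csv(outdir / "survival.csv"),
            heights=pd.read_csv(outdir / "heights.csv"),
        )
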