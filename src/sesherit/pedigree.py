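"""Pedigree structure, relative-pair classification and genome sharing.

A :class:`Pedigree` is a directed, acyclic parent->child graph annotated with
sex and twin zygosity.  It is the source of *expected* additive genetic
correlations between relatives (twice the kinship coefficient, e.g. 0.5 for
full siblings, 0.125 for first cousins, 1 for monozygotic twins) and of the
pair classification used by the family variance-component models.  *Empirical*
genome sharing between siblings is estimated from genotypes with the
within-family robust kinship estimator (heterozygote concordance vs opposite
homozygotes), the estimator implemented by KING's family mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

MISSING_PARENT = "0"

#: canonical relationship labels used throughout the package
REL_MZ = "MZ"
REL_DZ = "DZ"
REL_FULLSIB = "fullsib"
REL_COUSIN = "first_cousin"
REL_OTHER = "other"

#: expected additive genetic correlation per relationship class
EXPECTED_R_G = {REL_MZ: 1.0, REL_DZ: 0.5, REL_FULLSIB: 0.5, REL_COUSIN: 0.125}

_ZYG_RE = re.compile(r"^(MZ|DZ)(\S*)$")


@dataclass(frozen=True)
class RelativePair:
    """A classified pair of relatives.

    ``r_g`` is the expected genetic correlation from the pedigree unless it
    has been replaced by an empirical genome-sharing estimate.  ``r_c_label``
    names the environment-sharing class used by the ACE models: siblings and
    twins share a household (label ``"sib"``), first cousins share an extended
    family (label ``"cousin"``).
    """

    id1: str
    id2: str
    relationship: str
    r_g: float
    r_c_label: str = field(default="")

    def key(self) -> tuple[str, str]:
        return (self.id1, self.id2) if self.id1 <= self.id2 else (self.id2, self.id1)


class Pedigree:
    """Parent-child pedigree with sex and twin-zygosity annotations.

    Parameters
    ----------
    table:
        DataFrame with columns ``id, father, mother, sex, zygosity``.
        Missing parents are encoded ``"0"``; individuals must have either both
        or neither parent recorded.  ``sex`` is 1 (male) or 2 (female).
        ``zygosity`` is ``"0"`` for non-twins or ``"MZ<k>"`` / ``"DZ<k>"``
        where ``<k>`` indexes the twin set.
    """

    COLUMNS = ["id", "father", "mother", "sex", "zygosity"]

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"pedigree table missing columns: {missing}")
        for col in ("id", "father", "mother", "zygosity"):
            df[col] = df[col].astype(str)
        df["sex"] = df["sex"].astype(int)
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate individual id: {dup}")
        self.table = df.reset_index(drop=True)
        ids = set(df["id"])
        self._father: dict[str, str | None] = {}
        self._mother: dict[str, str | None] = {}
        for row in df.itertuples(index=False):
            f = None if row.father == MISSING_PARENT else row.father
            m = None if row.mother == MISSING_PARENT else row.mother
            if (f is None) != (m is None):
                raise ValueError(f"individual {row.id} has exactly one recorded parent")
            for p in (f, m):
                if p is not None and p not in ids:
                    raise ValueError(f"parent {p} of {row.id} not in pedigree")
            self._father[row.id] = f
            self._mother[row.id] = m
        self._sex = dict(zip(df["id"], df["sex"]))
        self._zyg = dict(zip(df["id"], df["zygosity"]))
        self._validate_acyclic()
        self._validate_twins()
        self._depth_cache: dict[str, int] = {}
        self._kin_cache: dict[tuple[str, str], float] = {}

    # -- construction / IO -------------------------------------------------

    @classmethod
    def read_tsv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def concat(cls, pedigrees: Sequence["Pedigree"]) -> "Pedigree":
        """Stack disjoint pedigrees (ids must already be unique)."""
        return cls(pd.concat([p.table for p in pedigrees], ignore_index=True))

    # -- basic structure ---------------------------------------------------

    @property
    def individuals(self) -> list[str]:
        return list(self.table["id"])

    def sex(self, iid: str) -> int:
        return self._sex[iid]

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        return self._father[iid], self._mother[iid]

    def is_founder(self, iid: str) -> bool:
        return self._father[iid] is None

    @property
    def founders(self) -> list[str]:
        return [i for i in self.individuals if self.is_founder(i)]

    def leaves(self) -> list[str]:
        """Individuals that are nobody's recorded parent (the study cohort)."""
        parents = set(self._father.values()) | set(self._mother.values())
        parents.discard(None)
        return [i for i in self.individuals if i not in parents]

    def depth(self, iid: str) -> int:
        """Generation depth: 0 for founders, 1 + max(parent depths) otherwise."""
        d = self._depth_cache.get(iid)
        if d is None:
            f = self._father[iid]
            d = 0 if f is None else 1 + max(self.depth(f), self.depth(self._mother[iid]))
            self._depth_cache[iid] = d
        return d

    def twin_set(self, iid: str) -> str | None:
        z = self._zyg.get(iid, "0")
        return z if _ZYG_RE.match(z) else None

    def zygosity(self, iid: str) -> str | None:
        ts = self.twin_set(iid)
        return ts[:2] if ts else None

    def _validate_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for child, f in self._father.items():
            if f is not None:
                g.add_edge(f, child)
                g.add_edge(self._mother[child], child)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("pedigree contains a parent-child cycle")

    def _validate_twins(self) -> None:
        sets: dict[str, list[str]] = {}
        for iid in self.individuals:
            ts = self.twin_set(iid)
            if ts:
                sets.setdefault(ts, []).append(iid)
        for ts, members in sets.items():
            if len(members) != 2:
                raise ValueError(f"twin set {ts} has {len(members)} members (need 2)")
            pa = {self.parents(m) for m in members}
            if len(pa) != 1:
                raise ValueError(f"twin set {ts} members have different parents")
            if ts.startswith("MZ"):
                sexes = {self.sex(m) for m in members}
                if len(sexes) != 1:
                    raise ValueError(f"MZ twin set {ts} members differ in sex")
        self._twin_sets = sets

    # -- kinship -----------------------------------------------------------

    def _genome_rep(self, iid: str) -> str:
        # MZ co-twins carry the same genome: collapse each MZ set onto one
        # representative so kinship treats them as genetically identical.
        ts = self.twin_set(iid)
        if ts and ts.startswith("MZ"):
            return min(self._twin_sets[ts])
        return iid

    def kinship(self, id1: str, id2: str) -> float:
        """Kinship coefficient phi via the recursive founder-based algorithm.

        Founders are assumed unrelated and non-inbred; MZ co-twins are
        genetically identical.
        """
        for i in (id1, id2):
            if i not in self._sex:
                raise KeyError(f"unknown individual: {i}")
        return self._phi(self._genome_rep(id1), self._genome_rep(id2))

    def _phi(self, a: str, b: str) -> float:
        if a == b:
            return 0.5
        key = (a, b) if a <= b else (b, a)
        cached = self._kin_cache.get(key)
        if cached is not None:
            return cached
        # recurse on the deeper individual so the recursion terminates at founders
        if self.depth(a) < self.depth(b):
            a, b = b, a
        if self.is_founder(a):
            val = 0.0
        else:
            fa = self._genome_rep(self._father[a])
            mo = self._genome_rep(self._mother[a])
            val = 0.5 * (self._phi(fa, b) + self._phi(mo, b))
        self._kin_cache[key] = val
        return val

    def expected_relatedness(self, id1: str, id2: str) -> float:
        """Expected additive genetic correlation: twice the kinship coefficient."""
        return 2.0 * self.kinship(id1, id2)

    # -- pair classification -----------------------------------------------

    def classify_pairs(self, cohort: Iterable[str] | str | None = None) -> list[RelativePair]:
        """Enumerate MZ, DZ, full-sibling and first-cousin pairs once each.

        Pairs are formed among the study cohort — by default the leaf
        generation, i.e. the phenotyped individuals; ancestors serve only to
        establish the relationships.  Pass ``cohort="all"`` to classify over
        everyone, or an explicit iterable of ids.
        """
        if cohort is None:
            members = self.leaves()
        elif isinstance(cohort, str):
            if cohort != "all":
                raise ValueError("cohort must be None, 'all' or an iterable of ids")
            members = self.individuals
        else:
            members = list(cohort)
            unknown = [m for m in members if m not in self._sex]
            if unknown:
                raise KeyError(f"unknown individuals in cohort: {unknown[:3]}")
        member_set = set(members)

        sibships: dict[tuple[str, str], list[str]] = {}
        for iid in members:
            f, m = self.parents(iid)
            if f is not None:
                sibships.setdefault((f, m), []).append(iid)

        pairs: list[RelativePair] = []
        seen: set[tuple[str, str]] = set()

        def add(i: str, j: str, rel: str) -> None:
            key = (i, j) if i <= j else (j, i)
            if key in seen:
                return
            seen.add(key)
            label = "cousin" if rel == REL_COUSIN else "sib"
            pairs.append(RelativePair(key[0], key[1], rel, EXPECTED_R_G[rel], label))

        # within-sibship pairs: twins or full sibs
        for sibs in sibships.values():
            for i_idx in range(len(sibs)):
                for j_idx in range(i_idx + 1, len(sibs)):
                    i, j = sibs[i_idx], sibs[j_idx]
                    tsi, tsj = self.twin_set(i), self.twin_set(j)
                    if tsi is not None and tsi == tsj:
                        add(i, j, REL_MZ if tsi.startswith("MZ") else REL_DZ)
                    else:
                        add(i, j, REL_FULLSIB)

        # cousin pairs: parents of the two sibships are full siblings
        couple_of: dict[str, tuple[str, str]] = {}
        for couple in sibships:
            for p in couple:
                f, m = self.parents(p)
                if f is not None:
                    couple_of[p] = (f, m)
        by_grandcouple: dict[tuple[str, str], list[tuple[tuple[str, str], str]]] = {}
        for couple in sibships:
            for p in couple:
                gc = couple_of.get(p)
                if gc is not None:
                    by_grandcouple.setdefault(gc, []).append((couple, p))
        for linked in by_grandcouple.values():
            for a_idx in range(len(linked)):
                for b_idx in range(a_idx + 1, len(linked)):
                    (ca, pa), (cb, pb) = linked[a_idx], linked[b_idx]
                    if ca == cb or pa == pb:
                        continue
                    for i in sibships[ca]:
                        for j in sibships[cb]:
                            if i == j:
                                continue
                            # double first cousins etc. fall outside the design
                            if abs(self.expected_relatedness(i, j) - 0.125) < 1e-12:
                                add(i, j, REL_COUSIN)
        pairs.sort(key=RelativePair.key)
        return pairs

    def relationship(self, id1: str, id2: str) -> str:
        """Classify a single pair (including ``other``)."""
        if id1 == id2:
            raise ValueError("an individual cannot be paired with itself")
        f1, m1 = self.parents(id1)
        f2, m2 = self.parents(id2)
        if f1 is not None and (f1, m1) == (f2, m2):
            ts1, ts2 = self.twin_set(id1), self.twin_set(id2)
            if ts1 is not None and ts1 == ts2:
                return REL_MZ if ts1.startswith("MZ") else REL_DZ
            return REL_FULLSIB
        r = self.expected_relatedness(id1, id2)
        if abs(r - 0.125) < 1e-12 and f1 is not None and f2 is not None:
            parents1, parents2 = {f1, m1}, {f2, m2}
            for p in parents1:
                for q in parents2:
                    fp, mp = self.parents(p)
                    if fp is not None and (fp, mp) == self.parents(q) and p != q:
                        return REL_COUSIN
        return REL_OTHER


def pairs_to_frame(pairs: Sequence[RelativePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id1": [p.id1 for p in pairs],
            "id2": [p.id2 for p in pairs],
            "relationship": [p.relationship for p in pairs],
            "r_g": [p.r_g for p in pairs],
            "r_c_label": [p.r_c_label for p in pairs],
        }
    )


def write_pairs_tsv(pairs: Sequence[RelativePair], path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


# -- empirical genome sharing ----------------------------------------------


def estimate_ibd_sharing(
    genos,
    pairs: Sequence[RelativePair] | pd.DataFrame,
    min_informative_snps: int = 1000,
) -> pd.DataFrame:
    """Empirical genome sharing r_g-hat = 2*phi-hat for each pair.

    Uses the within-family robust kinship estimator

        phi-hat = (N_het_both - 2 * N_opposite_hom) / (N_het(1) + N_het(2))

    where counts run over SNPs; the estimate is clipped to [0, 1].  Pairs with
    fewer than ``min_informative_snps`` heterozygous sites in the denominator
    are flagged unestimable (NaN r_hat).

    Parameters
    ----------
    genos:
        A :class:`~sesherit.simdata.GenotypeMatrix` (or anything with
        ``dosage`` (n x m, values 0/1/2) and ``sample_ids``).
    pairs:
        RelativePair sequence or DataFrame with ``id1``/``id2`` columns.

    Returns
    -------
    DataFrame with columns id1, id2, relationship, r_hat, n_informative.
    """
    if isinstance(pairs, pd.DataFrame):
        frame = pairs.copy()
    else:
        frame = pairs_to_frame(pairs)
    dosage = np.asarray(genos.dosage)
    index = {s: k for k, s in enumerate(genos.sample_ids)}
    i1 = np.array([index[s] for s in frame["id1"]])
    i2 = np.array([index[s] for s in frame["id2"]])

    het = dosage == 1
    n_het = het.sum(axis=1)
    r_hat = np.full(len(frame), np.nan)
    n_inf = np.zeros(len(frame), dtype=int)
    # chunked so pair-count x SNP-count boolean temporaries stay modest
    chunk = max(1, int(2e8) // max(dosage.shape[1], 1))
    for start in range(0, len(frame), chunk):
        sl = slice(start, min(start + chunk, len(frame)))
        a, b = dosage[i1[sl]], dosage[i2[sl]]
        n_both_het = ((a == 1) & (b == 1)).sum(axis=1)
        n_opp = (np.abs(a.astype(np.int16) - b.astype(np.int16)) == 2).sum(axis=1)
        denom = n_het[i1[sl]] + n_het[i2[sl]]
        n_inf[sl] = denom
        ok = denom >= max(min_informative_snps, 1)
        phi = np.full(len(denom), np.nan)
        phi[ok] = (n_both_het[ok] - 2.0 * n_opp[ok]) / denom[ok]
        r_hat[sl] = np.clip(2.0 * phi, 0.0, 1.0)
    out = frame[[c for c in ("id1", "id2", "relationship") if c in frame.columns]].copy()
    out["r_hat"] = r_hat
    out["n_informative"] = n_inf
    return out
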