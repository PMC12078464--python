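import numpy as np
import pandas as pd
import pytest

from sesherit import Pedigree


def make_pedigree(rows):
    """rows: (id, father, mother, sex, zygosity)."""
    return Pedigree(
        pd.DataFrame(rows, columns=["id", "father", "mother", "sex", "zygosity"])
    )


@pytest.fixture
def nuclear_family():
    """Two founders with two offspring."""
    return make_pedigree(
        [
            ("f", "0", "0", 1, "0"),
            ("m", "0", "0", 2, "0"),
            ("a", "f", "m", 1, "0"),
            ("b", "f", "m", 2, "0"),
        ]
    )


@pytest.fixture
def cousin_pedigree():
    """Three generations: two sibling parents, each mated to an unrelated
    founder, one child each — the grandchildren are first cousins."""
    return make_pedigree(
        [
            ("gpa", "0", "0", 1, "0"),
            ("gma", "0", "0", 2, "0"),
            ("p1", "gpa", "gma", 1, "0"),
            ("p2", "gpa", "gma", 1, "0"),
            ("s1", "0", "0", 2, "0"),
            ("s2", "0", "0", 2, "0"),
            ("c1", "p1", "s1", 1, "0"),
            ("c2", "p2", "s2", 2, "0"),
        ]
    )


@pytest.fixture
def two_sibship_pedigree():
    """Ten persons: the cousin pedigree with sibships of two grandchildren."""
    return make_pedigree(
        [
            ("gpa", "0", "0", 1, "0"),
            ("gma", "0", "0", 2, "0"),
            ("p1", "gpa", "gma", 1, "0"),
            ("p2", "gpa", "gma", 1, "0"),
            ("s1", "0", "0", 2, "0"),
            ("s2", "0", "0", 2, "0"),
            ("c1a", "p1", "s1", 1, "0"),
            ("c1b", "p1", "s1", 2, "0"),
            ("c2a", "p2", "s2", 1, "0"),
            ("c2b", "p2", "s2", 2, "0"),
        ]
    )


@pytest.fixture
def halfsib_pedigree():
    """Shared father, different unrelated mothers."""
    return make_pedigree(
        [
            ("f", "0", "0", 1, "0"),
            ("m1", "0", "0", 2, "0"),
            ("m2", "0", "0", 2, "0"),
            ("h1", "f", "m1", 1, "0"),
            ("h2", "f", "m2", 2, "0"),
        ]
    )


def gene_drop_correlation(ped, id1, id2, n_drops=100_000, seed=0, p=0.5):
    """Independent Monte-Carlo oracle for expected additive relatedness.

    Drops one biallelic locus through the pedigree ``n_drops`` times (each
    drop fully independent, founders Bernoulli(p) per allele) and returns the
    empirical correlation of the two individuals' allele counts.  Written
    from scratch so it shares no code with the kinship implementation.
    """
    rng = np.random.default_rng(seed)
    ids = ped.individuals
    order = sorted(ids, key=ped.depth)
    alleles = {}
    for iid in order:
        f, m = ped.parents(iid)
        if f is None:
            alleles[iid] = rng.random((n_drops, 2)) < p
        else:
            pat = alleles[f][np.arange(n_drops), rng.integers(0, 2, n_drops)]
            mat = alleles[m][np.arange(n_drops), rng.integers(0, 2, n_drops)]
            alleles[iid] = np.column_stack([pat, mat])
    d1 = alleles[id1].sum(axis=1)
    d2 = alleles[id2].sum(axis=1)
    return float(np.corrcoef(d1, d2)[0, 1])
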