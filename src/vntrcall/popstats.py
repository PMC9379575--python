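"""Cohort-level summaries of VNTR motif-count genotypes.

Operates on a tidy genotype table (one row per individual x locus with
two positive integer alleles and a population label): Hardy-Weinberg
equilibrium filtering, polymorphism classification, the fraction of
loci whose consensus motif length is a multiple of three (in-frame
motif-count changes), normalised allele entropy per population, and a
PCA-ready allele matrix export.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

GENOTYPE_COLUMNS = ["individual", "locus_id", "allele1", "allele2"]


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in GENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"genotype table missing columns: {missing}")


def hwe_test(genotypes: Iterable[tuple[int, int]]) -> float:
    """Chi-squared goodness-of-fit p-value against Hardy-Weinberg.

    Observed unordered genotype counts are compared with expectations
    from the allele frequencies; genotype classes with expected count
    below 1 are pooled into one class; degrees of freedom are
    ``g - a`` (genotype classes minus alleles).  Monomorphic loci pass
    trivially with p = 1.
    """
    obs = Counter(tuple(sorted(g)) for g in genotypes)
    n = sum(obs.values())
    if n == 0:
        raise ValueError("no genotypes")
    allele_counts = Counter()
    for (a1, a2), cnt in obs.items():
        allele_counts[a1] += cnt
        allele_counts[a2] += cnt
    alleles = sorted(allele_counts)
    if len(alleles) < 2:
        return 1.0
    freqs = {a: allele_counts[a] / (2 * n) for a in alleles}
    expected = {}
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            e = n * (freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b])
            expected[(a, b)] = e
    # pool classes with expected < 1
    kept, pool_e, pool_o = {}, 0.0, 0
    for cls, e in expected.items():
        if e < 1.0:
            pool_e += e
            pool_o += obs.get(cls, 0)
        else:
            kept[cls] = (obs.get(cls, 0), e)
    stat = sum((o - e) ** 2 / e for o, e in kept.values())
    g = len(kept)
    if pool_e > 0:
        stat += (pool_o - pool_e) ** 2 / pool_e
        g += 1
    df = g - len(alleles)
    if df <= 0:
        return 1.0
    return float(chi2.sf(stat, df=df))


def filter_hwe(table: pd.DataFrame, cutoff: float = 0.05) -> list[str]:
    """Locus ids whose genotype distribution passes the HWE test."""
    _check_table(table)
    kept = []
    for locus_id, grp in table.groupby("locus_id", sort=True):
        gts = list(zip(grp["allele1"].astype(int), grp["allele2"].astype(int)))
        if hwe_test(gts) >= cutoff:
            kept.append(str(locus_id))
    return kept


def polymorphic_loci(table: pd.DataFrame,
                     ref_alleles: Mapping[str, int],
                     min_carrier_fraction: float = 0.01) -> set[str]:
    """Loci where >= 1% of individuals carry a non-reference allele."""
    _check_table(table)
    out = set()
    for locus_id, grp in table.groupby("locus_id", sort=True):
        ref = int(ref_alleles[str(locus_id)])
        carriers = ((grp["allele1"].astype(int) != ref)
                    | (grp["allele2"].astype(int) != ref)).sum()
        if len(grp) and carriers / len(grp) >= min_carrier_fraction:
            out.add(str(locus_id))
    return out


def zero_mod3_fraction(motif_lengths: Iterable[int]) -> float:
    """Fraction of consensus motif lengths that are multiples of three."""
    lengths = [int(x) for x in motif_lengths]
    if not lengths:
        raise ValueError("zero_mod3_fraction is undefined on an empty set")
    return sum(1 for w in lengths if w % 3 == 0) / len(lengths)


def normalized_entropy(allele_counts: Iterable[int]) -> float:
    """Shannon entropy of the allele distribution, normalised to [0, 1].

    ``-sum(p_i ln p_i) / ln(n)`` with ``n`` the number of distinct
    observed alleles; defined as 0 for a single observed allele.
    """
    counts = np.asarray([c for c in allele_counts if c > 0], dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("allele counts must contain a positive total")
    if counts.size == 1:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / math.log(counts.size))


def population_entropy_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(locus, population) normalised allele entropy."""
    _check_table(table)
    if "population" not in table.columns:
        raise ValueError("population column required")
    rows = {}
    for (locus_id, pop), grp in table.groupby(["locus_id", "population"]):
        alleles = Counter(grp["allele1"].astype(int)) \
            + Counter(grp["allele2"].astype(int))
        rows.setdefault(str(locus_id), {})[str(pop)] = \
            normalized_entropy(alleles.values())
    return pd.DataFrame(rows).T.sort_index()


def allele_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Individuals x loci matrix of summed allele motif counts (PCA input)."""
    _check_table(table)
    df = table.copy()
    df["value"] = df["allele1"].astype(int) + df["allele2"].astype(int)
    return df.pivot_table(index="individual", columns="locus_id",
                          values="value", aggfunc="first")
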