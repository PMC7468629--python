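"""Locus- and population-level differentiation statistics.

Implements the Weir & Cockerham (1984) theta estimator of F_st (locus-wise
variance components and the ratio-of-sums multilocus combination),
Rosenberg's informativeness for assignment I_n with its per-population
divergence (PSD) decomposition, and Nei's D_A genetic distance.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable

Counts = tuple[int, int, int]


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def wc_components(counts_per_pop: Sequence[Counts]) -> tuple[float, float, float]:
    """Weir-Cockerham variance components (a, b, c) for one biallelic locus.

    ``counts_per_pop`` holds one ``(n_II, n_ID, n_DD)`` triple per population;
    heterozygosity enters through the observed heterozygote frequencies.
    """
    r = len(counts_per_pop)
    if r < 2:
        raise ValueError("need at least two populations")
    n_i = np.array([sum(c) for c in counts_per_pop], dtype=float)
    if (n_i == 0).any():
        raise ValueError("population with no observed genotypes")
    p_i = np.array([(2 * c[0] + c[1]) / (2 * n) for c, n in zip(counts_per_pop, n_i)])
    h_i = np.array([c[1] / n for c, n in zip(counts_per_pop, n_i)])

    nbar = n_i.mean()
    n_c = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)

    a = (nbar / n_c) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a), float(b), float(c)


def wc_theta_locus(counts_pop1: Counts, counts_pop2: Counts) -> float:
    """Two-population Weir-Cockerham theta at one locus.

    Returns NaN when both populations are monomorphic for the same allele
    (zero total variance; theta undefined).
    """
    a, b, c = wc_components([counts_pop1, counts_pop2])
    denom = a + b + c
    if denom == 0:
        return math.nan
    return a / denom


def multilocus_theta(table: GenotypeTable, pop_x: str, pop_y: str,
                     locus_set: Sequence[str] | None = None) -> float:
    """Ratio-of-sums multilocus theta between two populations."""
    sub = table if locus_set is None else table.subset_loci(locus_set)
    cx = sub.genotype_counts(pop_x)
    cy = sub.genotype_counts(pop_y)
    num = den = 0.0
    for i in range(sub.n_loci):
        a, b, c = wc_components([tuple(cx[i]), tuple(cy[i])])
        num += a
        den += a + b + c
    if den == 0:
        return math.nan
    return num / den


def pairwise_fst_matrix(table: GenotypeTable,
                        locus_set: Sequence[str] | None = None,
                        clamp_negative: bool = False) -> pd.DataFrame:
    """Populations x populations multilocus theta matrix (zero diagonal)."""
    pops = table.populations
    m = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, x in enumerate(pops):
        for y in pops[i + 1:]:
            t = multilocus_theta(table, x, y, locus_set)
            if clamp_negative and t < 0:
                t = 0.0
            m.loc[x, y] = m.loc[y, x] = t
    return m


def locus_fst_table(table: GenotypeTable, groups: dict[str, list[str]] | None = None,
                    clamp_negative: bool = False) -> pd.DataFrame:
    """Per-locus two-population theta for every pair of (pooled) groups.

    ``groups`` maps a group label to the population labels pooled into it
    (individuals are merged before estimation); default is one group per
    population label.  Rows are loci, columns ``"X-Y"`` pairs.
    """
    if groups is None:
        groups = {p: [p] for p in table.populations}
    counts = {g: sum_counts(table, pops) for g, pops in groups.items()}
    labels = list(groups)
    data = {}
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            col = []
            for ell in range(table.n_loci):
                t = wc_theta_locus(tuple(counts[x][ell]), tuple(counts[y][ell]))
                if clamp_negative and not math.isnan(t) and t < 0:
                    t = 0.0
                col.append(t)
            data[f"{x}-{y}"] = col
    return pd.DataFrame(data, index=table.locus_ids)


def sum_counts(table: GenotypeTable, pops: Sequence[str]) -> np.ndarray:
    """Pooled per-locus genotype counts over several population labels."""
    total = np.zeros((table.n_loci, 3), dtype=np.int64)
    for p in pops:
        total += table.genotype_counts(p)
    return total


def count_loci_above(fst_table: pd.DataFrame, threshold: float) -> pd.Series:
    """Per column (pair), number of loci with theta strictly above threshold."""
    return (fst_table > threshold).sum(axis=0)


# ---------------------------------------------------------------------------
# Rosenberg's informativeness for assignment
# ---------------------------------------------------------------------------

def _xlogx(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    nz = x > 0
    out[nz] = x[nz] * np.log(x[nz])
    return out


def rosenberg_in(freqs: Sequence[float]) -> float:
    """Informativeness for assignment I_n (nats) at one biallelic locus.

    ``freqs`` holds the insertion frequency in each of K populations.  The
    unweighted mean frequency defines the pooled distribution; 0*log(0) = 0.
    """
    p = np.asarray(freqs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    k = len(p)
    alleles = np.stack([p, 1 - p])             # (2, K)
    pbar = alleles.mean(axis=1)                # (2,)
    value = (-_xlogx(pbar)).sum() + _xlogx(alleles).sum() / k
    return float(max(value, 0.0))


def psd_values(freqs: Sequence[float], base: float = 2.0) -> np.ndarray:
    """Per-population divergence from the pooled allele distribution.

    PSD_i is the Kullback-Leibler divergence of population i's allele
    distribution from the unweighted mean distribution, in log-``base``
    units.  The mean PSD over populations converted to nats equals I_n.
    """
    p = np.asarray(freqs, dtype=float)
    alleles = np.stack([p, 1 - p])
    pbar = alleles.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(alleles > 0, alleles / pbar, 1.0)
        kl = (alleles * np.log(ratio)).sum(axis=0)
    return np.maximum(kl, 0.0) / math.log(base)


def convert_log_base(value: float, from_base: float, to_base: float) -> float:
    """Rescale an information value between logarithm bases."""
    return value * math.log(from_base) / math.log(to_base)


def informativeness_table(table: GenotypeTable,
                          groups: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Per-locus I_n (nats) and per-group PSD (bits).

    Columns: ``in_nats`` then ``psd_<group>`` per group.
    """
    if groups is None:
        groups = {p: [p] for p in table.populations}
    freq_by_group = {}
    for g, pops in groups.items():
        c = sum_counts(table, pops)
        denom = 2 * c.sum(axis=1)
        freq_by_group[g] = np.where(denom > 0, (2 * c[:, 0] + c[:, 1]) / denom, np.nan)
    labels = list(groups)
    rows = []
    for ell in range(table.n_loci):
        f = [freq_by_group[g][ell] for g in labels]
        row = {"in_nats": rosenberg_in(f)}
        for g, v in zip(labels, psd_values(f)):
            row[f"psd_{g}"] = v
        rows.append(row)
    return pd.DataFrame(rows, index=table.locus_ids)


# ---------------------------------------------------------------------------
# Nei's D_A
# ---------------------------------------------------------------------------

def nei_da(freq_x: Sequence[float], freq_y: Sequence[float]) -> float:
    """Nei's D_A distance from per-locus insertion frequencies.

    ``D_A = 1 - (1/L) * sum_loci sum_alleles sqrt(x_j * y_j)``.
    """
    x = np.asarray(freq_x, dtype=float)
    y = np.asarray(freq_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors differ in length")
    shared = np.sqrt(x * y) + np.sqrt((1 - x) * (1 - y))
    return float(1 - shared.mean())


def da_distance_matrix(table: GenotypeTable,
                       locus_set: Sequence[str] | None = None) -> pd.DataFrame:
    """Populations x populations Nei's D_A matrix (zero diagonal)."""
    sub = table if locus_set is None else table.subset_loci(locus_set)
    pops = sub.populations
    freqs = {p: sub.insertion_frequencies(p) for p in pops}
    m = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, x in enumerate(pops):
        for y in pops[i + 1:]:
            d = nei_da(freqs[x], freqs[y])
            m.loc[x, y] = m.loc[y, x] = d
    return m
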