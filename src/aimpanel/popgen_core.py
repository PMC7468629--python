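"""Per-locus allele frequencies, forensic parameters and Hardy-Weinberg tests.

All statistics are for biallelic loci with genotypes counted as
``(n_II, n_ID, n_DD)`` — insertion homozygote, heterozygote, deletion
homozygote.  Conventions:

* ``p`` is the insertion allele frequency; ``q = 1 - p``.
* Expected heterozygosity uses Nei's small-sample correction
  ``(2n/(2n-1)) * 2pq``.
* PIC is Botstein's formula specialized to two alleles, ``2pq - 2p^2q^2``.
* MP is the sum of squared observed genotype frequencies, PD its complement.
* PE = Ho^2 * (1 - 2*Ho*(1-Ho)^2); TPI = 1/(2*(1-Ho)).
* The exact HWE test conditions on the observed allele counts and sums the
  probabilities of all heterozygote counts as or less probable than observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .errors import DegenerateLocusError
from .io_formats import GenotypeTable

Counts = tuple[int, int, int]


@dataclass
class LocusFrequency:
    locus_id: str
    p: float
    n: int                      # diploid individuals with observed genotypes
    genotype_counts: Counts

    def __post_init__(self) -> None:
        n_ii, n_id, n_dd = self.genotype_counts
        if min(n_ii, n_id, n_dd) < 0:
            raise ValueError("negative genotype count")
        if n_ii + n_id + n_dd != self.n:
            raise ValueError("genotype counts do not sum to n")


@dataclass
class ForensicParameters:
    """One per-locus row of the forensic summary table."""

    locus_id: str
    p: float
    mp: float
    pd: float
    pic: float
    pe: float
    tpi: float
    ho: float
    he: float
    hwe_p: float


@dataclass
class HweResult:
    locus_id: str
    p_value: float
    method: str                  # "exact" | "chi2"
    monomorphic: bool = False
    bonferroni_alpha: float | None = None
    significant_after_correction: bool | None = None


def _validate_counts(counts: Counts) -> Counts:
    n_ii, n_id, n_dd = (int(c) for c in counts)
    if min(n_ii, n_id, n_dd) < 0:
        raise ValueError(f"negative genotype count: {counts}")
    if n_ii + n_id + n_dd == 0:
        raise DegenerateLocusError("locus has no observed genotypes")
    return n_ii, n_id, n_dd


def allele_frequency(counts: Counts, locus_id: str = "") -> LocusFrequency:
    """Insertion allele frequency from a genotype-count triple."""
    n_ii, n_id, n_dd = _validate_counts(counts)
    n = n_ii + n_id + n_dd
    p = (2 * n_ii + n_id) / (2 * n)
    return LocusFrequency(locus_id, p, n, (n_ii, n_id, n_dd))


def observed_heterozygosity(counts: Counts) -> float:
    n_ii, n_id, n_dd = _validate_counts(counts)
    return n_id / (n_ii + n_id + n_dd)


def expected_heterozygosity_unbiased(p: float, n: int) -> float:
    """Nei's unbiased expected heterozygosity ``(2n/(2n-1)) * 2pq``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return (2 * n / (2 * n - 1)) * 2 * p * (1 - p)


def pic_biallelic(p: float) -> float:
    q = 1 - p
    return 2 * p * q - 2 * p * p * q * q


def match_probability(counts: Counts) -> tuple[float, float]:
    """(MP, PD): sum of squared observed genotype frequencies and complement."""
    n_ii, n_id, n_dd = _validate_counts(counts)
    n = n_ii + n_id + n_dd
    mp = (n_ii / n) ** 2 + (n_id / n) ** 2 + (n_dd / n) ** 2
    return mp, 1 - mp


def power_of_exclusion(ho: float) -> float:
    h, big_h = ho, 1 - ho
    return h * h * (1 - 2 * h * big_h * big_h)


def typical_paternity_index(ho: float) -> float:
    if ho >= 1:
        raise ValueError("TPI undefined at Ho = 1")
    return 1 / (2 * (1 - ho))


# ---------------------------------------------------------------------------
# Hardy-Weinberg testing
# ---------------------------------------------------------------------------

def _log_het_prob(n: int, n_a: int, n_ab: int) -> float:
    """log P(n_ab heterozygotes | n individuals, n_a copies of allele A).

    Levene's conditional distribution:
    P = n! / (n_AA! n_ab! n_BB!) * 2^n_ab * n_A! n_B! / (2n)!
    """
    n_aa = (n_a - n_ab) // 2
    n_bb = n - n_aa - n_ab
    n_b = 2 * n - n_a
    return (gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(n_ab + 1) - gammaln(n_bb + 1)
            + n_ab * np.log(2) + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))


def hwe_exact_p(counts: Counts) -> float:
    """Exact biallelic HWE P: total probability of tables as or less likely
    than the observed one, conditional on the allele counts."""
    n_ii, n_id, n_dd = _validate_counts(counts)
    n = n_ii + n_id + n_dd
    n_a = 2 * n_ii + n_id
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    n_a_eff = min(n_a, 2 * n - n_a)
    start = n_a_eff % 2
    hets = np.arange(start, n_a_eff + 1, 2)
    logps = np.array([_log_het_prob(n, n_a, h) for h in hets])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    obs = probs[np.nonzero(hets == n_id)[0][0]]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def hwe_chi2_p(counts: Counts) -> float:
    """One-degree-of-freedom chi-square HWE test (no continuity correction)."""
    n_ii, n_id, n_dd = _validate_counts(counts)
    n = n_ii + n_id + n_dd
    p = (2 * n_ii + n_id) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    q = 1 - p
    exp = np.array([n * p * p, n * 2 * p * q, n * q * q])
    obs = np.array([n_ii, n_id, n_dd], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2_dist.sf(stat, df=1))


def hwe_test(counts: Counts, method: str = "exact", locus_id: str = "") -> HweResult:
    if method not in ("exact", "chi2"):
        raise ValueError(f"unknown HWE method {method!r}")
    n_ii, n_id, n_dd = _validate_counts(counts)
    n = n_ii + n_id + n_dd
    n_a = 2 * n_ii + n_id
    if n_a == 0 or n_a == 2 * n:
        return HweResult(locus_id, 1.0, method, monomorphic=True)
    p = hwe_exact_p(counts) if method == "exact" else hwe_chi2_p(counts)
    return HweResult(locus_id, p, method)


def bonferroni_correct(p_values, alpha: float = 0.05) -> list[bool]:
    """Per-locus significance flags at the Bonferroni-corrected threshold
    ``alpha / L``."""
    p_values = list(p_values)
    if not p_values:
        return []
    threshold = alpha / len(p_values)
    return [p < threshold for p in p_values]


# ---------------------------------------------------------------------------
# whole-table driver
# ---------------------------------------------------------------------------

def forensic_parameters_from_counts(counts: Counts, locus_id: str = "",
                                    hwe_method: str = "exact") -> ForensicParameters:
    freq = allele_frequency(counts, locus_id)
    ho = observed_heterozygosity(counts)
    mp, pd = match_probability(counts)
    return ForensicParameters(
        locus_id=locus_id,
        p=freq.p,
        mp=mp,
        pd=pd,
        pic=pic_biallelic(freq.p),
        pe=power_of_exclusion(ho),
        tpi=typical_paternity_index(ho),
        ho=ho,
        he=expected_heterozygosity_unbiased(freq.p, freq.n),
        hwe_p=hwe_test(counts, hwe_method, locus_id).p_value,
    )


def forensic_table(table: GenotypeTable, hwe_method: str = "exact"):
    """Forensic parameters for every locus plus an unweighted means row.

    Returns a pandas DataFrame indexed by locus id (last row ``"mean"``) with
    columns ``mp, pd, pic, pe, tpi, ho, he, hwe_p, insertion, deletion``.
    """
    import pandas as pd

    counts = table.genotype_counts()
    rows = []
    for locus, c in zip(table.locus_ids, counts):
        fp = forensic_parameters_from_counts(tuple(c), locus, hwe_method)
        rows.append({
            "locus": locus, "mp": fp.mp, "pd": fp.pd, "pic": fp.pic, "pe": fp.pe,
            "tpi": fp.tpi, "ho": fp.ho, "he": fp.he, "hwe_p": fp.hwe_p,
            "insertion": fp.p, "deletion": 1 - fp.p,
        })
    df = pd.DataFrame(rows).set_index("locus")
    df.loc["mean"] = df.mean(axis=0)
    return df


def reconstruct_counts(p: float, ho: float, n: int) -> Counts:
    """Rebuild integer genotype counts from rounded ``(p, Ho, n)`` summaries.

    ``n_ID = round(Ho*n)`` and insertion-copy total ``round(p*2n)`` must have
    matching parity or the summaries are inconsistent.
    """
    n_id = round(ho * n)
    n_ins = round(p * 2 * n)
    if (n_ins - n_id) % 2:
        raise ValueError(f"inconsistent rounded summaries: p={p}, Ho={ho}, n={n}")
    n_ii = (n_ins - n_id) // 2
    n_dd = n - n_ii - n_id
    if min(n_ii, n_dd) < 0:
        raise ValueError(f"impossible rounded summaries: p={p}, Ho={ho}, n={n}")
    return n_ii, n_id, n_dd
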