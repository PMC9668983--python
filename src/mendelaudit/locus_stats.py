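"""Per-locus population statistics and dataset-level genotyping-error rates.

For each locus: allele frequencies over all called genotypes, minor-allele
frequency, observed/expected heterozygosity, the heterozygote deficiency
index F_IS = (He - Ho)/He with He = 2pq, and the exact conditional
Hardy-Weinberg test on the heterozygote count (two-sided by probability
mass, no mid-p correction -- the classical SNP-HWE construction).

Dataset-level rates follow the per-locus / per-allele error-rate framework
for replicated genotypes: with m_l loci carrying at least one mismatch,
m_a total allelic mismatches and nt = n_loci x n_individuals single-locus
genotypes, e_l = m_l / n_loci and e_a = m_a / (2 nt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_pedigree import GenotypeTable

__all__ = [
    "LocusSummary",
    "ErrorRateSummary",
    "genotype_counts",
    "hw_exact_p",
    "summarize_locus",
    "summarize_table",
    "error_rates",
    "error_rates_from_counts",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class LocusSummary:
    locus_id: Optional[str]
    n_called: int
    p: float  # frequency of allele1
    q: float  # frequency of allele2
    major_allele: int  # 1 or 2 (ties at 0.5 -> allele1)
    maf: float
    ho: float
    he: float
    f_is: float  # NaN when He == 0
    hw_p: float


@dataclass(frozen=True)
class ErrorRateSummary:
    m_l: int  # loci with >=1 mismatch
    m_a: int  # total allelic mismatches
    nt: int  # replicated single-locus genotypes = n_loci x n_individuals
    e_l: float  # m_l / n_loci
    e_a: float  # m_a / (2 nt)
    unique_loci_count: int
    unique_contribution: float  # unique loci / n_loci


def genotype_counts(calls: np.ndarray) -> tuple[int, int, int]:
    """Counts of (hom allele1, het, hom allele2) among called genotypes."""
    calls = np.asarray(calls)
    called = calls >= 0
    return (
        int(np.count_nonzero(calls[called] == 0)),
        int(np.count_nonzero(calls[called] == 1)),
        int(np.count_nonzero(calls[called] == 2)),
    )


def hw_exact_p(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Exact Hardy-Weinberg p-value conditional on the minor-allele count.

    Sums, over all heterozygote counts compatible with the observed sample
    size and minor-allele count, the conditional probabilities that are no
    larger than that of the observed heterozygote count. Returns a value in
    (0, 1]; monomorphic samples give exactly 1.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("need at least one called genotype")
    n_minor = min(2 * n_AA + n_AB, 2 * n_BB + n_AB)
    if n_minor == 0:
        return 1.0
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hom_minor - hets
    logw = (
        hets * _LN2
        - gammaln(hom_minor + 1.0)
        - gammaln(hets + 1.0)
        - gammaln(hom_major + 1.0)
    )
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    p_obs = probs[hets == n_AB][0]
    # tolerate fp ties between equal-probability configurations
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def summarize_locus(
    calls_at_locus: np.ndarray, locus_id: Optional[str] = None
) -> LocusSummary:
    """Summarize one locus from its call vector (codes 0/1/2, -1 missing)."""
    n0, n1, n2 = genotype_counts(calls_at_locus)
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError(f"locus {locus_id!r}: all calls missing")
    q = (2 * n2 + n1) / (2 * n)
    p = 1.0 - q
    major = 1 if q <= 0.5 else 2
    maf = min(p, q)
    ho = n1 / n
    he = 2.0 * p * q
    f_is = (he - ho) / he if he > 0 else float("nan")
    return LocusSummary(
        locus_id=locus_id,
        n_called=n,
        p=p,
        q=q,
        major_allele=major,
        maf=maf,
        ho=ho,
        he=he,
        f_is=f_is,
        hw_p=hw_exact_p(n0, n1, n2),
    )


def summarize_table(genotypes: GenotypeTable) -> pd.DataFrame:
    """Per-locus summary for a whole genotype table.

    Returns a DataFrame indexed by locus_id with columns chrom, pos,
    n_called, p, q, major_allele, maf, ho, he, f_is, hw_p. Loci with no
    called genotypes raise, matching :func:`summarize_locus`.
    """
    calls = genotypes.calls
    n0 = (calls == 0).sum(axis=1)
    n1 = (calls == 1).sum(axis=1)
    n2 = (calls == 2).sum(axis=1)
    n = n0 + n1 + n2
    if (n == 0).any():
        bad = genotypes.loci[int(np.argmax(n == 0))].locus_id
        raise ValueError(f"locus {bad!r}: all calls missing")
    q = (2 * n2 + n1) / (2 * n)
    p = 1.0 - q
    ho = n1 / n
    he = 2.0 * p * q
    with np.errstate(divide="ignore", invalid="ignore"):
        f_is = np.where(he > 0, (he - ho) / np.where(he > 0, he, 1.0), np.nan)
    hw = np.array(
        [hw_exact_p(int(a), int(b), int(c)) for a, b, c in zip(n0, n1, n2)]
    )
    frame = genotypes.loci_frame().set_index("locus_id")
    return pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "pos": frame["pos"],
            "n_called": n,
            "p": p,
            "q": q,
            "major_allele": np.where(q <= 0.5, 1, 2).astype(int),
            "maf": np.minimum(p, q),
            "ho": ho,
            "he": he,
            "f_is": f_is,
            "hw_p": hw,
        },
        index=frame.index,
    )


def error_rates_from_counts(
    m_l: int,
    m_a: int,
    n_loci_total: int,
    n_individuals: int,
    unique_loci_count: int = 0,
) -> ErrorRateSummary:
    """Error-rate summary straight from component counts."""
    if n_loci_total < 1 or n_individuals < 1:
        raise ValueError("n_loci_total and n_individuals must be positive")
    nt = n_loci_total * n_individuals
    return ErrorRateSummary(
        m_l=m_l,
        m_a=m_a,
        nt=nt,
        e_l=m_l / n_loci_total,
        e_a=m_a / (2 * nt),
        unique_loci_count=unique_loci_count,
        unique_contribution=unique_loci_count / n_loci_total,
    )


def error_rates(meset, n_loci_total: int, n_individuals: int) -> ErrorRateSummary:
    """Error-rate summary for a scanned dataset.

    ``n_loci_total`` and ``n_individuals`` must cover the full retained SNP
    panel and typed population, not only the mismatch set.
    """
    return error_rates_from_counts(
        m_l=len(meset.loci),
        m_a=len(meset.events),
        n_loci_total=n_loci_total,
        n_individuals=n_individuals,
        unique_loci_count=len(meset.unique_loci),
    )
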