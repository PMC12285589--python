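"""Allele frequencies, genotype frequencies and the Hardy-Weinberg test.

All statistics are computed at full floating precision from raw genotype
counts; rounding to a printable precision is a reporting concern handled in
:mod:`caseinpop.report`.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

from .genotype_io import GenotypeCounts

__all__ = [
    "AlleleFrequencies",
    "GenotypeFrequencySummary",
    "HWEResult",
    "allele_frequencies",
    "genotype_frequencies",
    "hwe_expected_counts",
    "hwe_test",
]

#: Expected genotype counts below this trigger a small-sample warning flag.
LOW_EXPECTED_COUNT = 5.0


@dataclass(frozen=True)
class AlleleFrequencies:
    """A1/A2 allele frequencies estimated by gene counting.

    ``p`` is the A1 frequency, ``q = 1 - p`` the A2 frequency, and
    ``n_alleles_sampled = 2N`` the number of gene copies behind the estimate.
    """

    p: float
    q: float
    n_alleles_sampled: int


@dataclass(frozen=True)
class GenotypeFrequencySummary:
    """Observed genotype frequencies and counts for one group."""

    label: str
    observed_counts: tuple[int, int, int]
    observed_freqs: tuple[float, float, float]


@dataclass(frozen=True)
class HWEResult:
    """Three-class chi-square test of Hardy-Weinberg proportions.

    ``valid`` is False for a monomorphic group (one allele absent), where the
    test is undefined and ``p_value`` is ``None``.  ``low_expected`` flags any
    expected class count below 5 — the statistic is still computed, but its
    chi-square approximation is fragile there.
    """

    expected_counts: tuple[float, float, float]
    expected_freqs: tuple[float, float, float]
    chi_square: float | None
    df: int
    p_value: float | None
    valid: bool
    low_expected: bool = False


def allele_frequencies(counts: GenotypeCounts) -> AlleleFrequencies:
    """Estimate p(A1) and q(A2) by gene counting: p = (2*n11 + n12) / 2N."""
    if counts.n < 1:
        raise ValueError(f"group {counts.label!r}: N must be >= 1")
    two_n = 2 * counts.n
    p = (2 * counts.n11 + counts.n12) / two_n
    return AlleleFrequencies(p=p, q=1.0 - p, n_alleles_sampled=two_n)


def genotype_frequencies(counts: GenotypeCounts) -> GenotypeFrequencySummary:
    """Observed genotype frequencies: counts divided by N."""
    if counts.n < 1:
        raise ValueError(f"group {counts.label!r}: N must be >= 1")
    n = counts.n
    return GenotypeFrequencySummary(
        label=counts.label,
        observed_counts=counts.as_tuple(),
        observed_freqs=(counts.n11 / n, counts.n12 / n, counts.n22 / n),
    )


def hwe_expected_counts(freqs: AlleleFrequencies, n: int) -> tuple[float, float, float]:
    """Hardy-Weinberg expected genotype counts (N*p^2, N*2pq, N*q^2)."""
    if n < 1:
        raise ValueError("N must be >= 1")
    p, q = freqs.p, freqs.q
    return (n * p * p, n * 2.0 * p * q, n * q * q)


def hwe_test(counts: GenotypeCounts) -> HWEResult:
    """Chi-square goodness-of-fit of observed genotypes to HWE proportions.

    Three genotype classes, two estimated allele frequencies with one free
    parameter, hence df = 1.  No continuity correction is applied.  The
    p-value is the upper tail of the chi-square(1) distribution.

    For a monomorphic group the expected heterozygote and minor-homozygote
    classes are empty and the test is undefined: the result carries
    ``valid=False`` and ``p_value=None``.
    """
    freqs = allele_frequencies(counts)
    expected = hwe_expected_counts(freqs, counts.n)
    p, q = freqs.p, freqs.q
    expected_freqs = (p * p, 2.0 * p * q, q * q)

    if p == 0.0 or q == 0.0:
        return HWEResult(
            expected_counts=expected,
            expected_freqs=expected_freqs,
            chi_square=None,
            df=1,
            p_value=None,
            valid=False,
        )

    chi_sq = sum(
        (obs - exp) ** 2 / exp for obs, exp in zip(counts.as_tuple(), expected)
    )
    return HWEResult(
        expected_counts=expected,
        expected_freqs=expected_freqs,
        chi_square=chi_sq,
        df=1,
        p_value=float(chi2.sf(chi_sq, df=1)),
        valid=True,
        low_expected=min(expected) < LOW_EXPECTED_COUNT,
    )
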