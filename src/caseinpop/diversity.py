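"""Per-group genetic diversity indices for a biallelic locus.

The summary mirrors the classic GenAlEx per-population panel: sample size N,
observed allele count Na, effective allele count Ne = 1/sum(p_i^2), Shannon
information index I = -sum(p_i ln p_i) in nats, observed heterozygosity
Ho = n12/N, expected heterozygosity (gene diversity) He = 2pq, the
small-sample unbiased variant uHe = He * 2N/(2N-1), and the fixation index
F = 1 - Ho/He (undefined when He = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce
from typing import Sequence

from .genotype_io import GenotypeCounts
from .locus_stats import allele_frequencies

__all__ = ["DiversitySummary", "diversity_summary", "pooled_summary"]


@dataclass(frozen=True)
class DiversitySummary:
    """One row of the per-group diversity panel.

    ``fixation_index`` is ``None`` for a monomorphic group (He = 0).
    """

    label: str
    n: int
    na: int
    ne: float
    shannon_i: float
    ho: float
    he: float
    uhe: float
    fixation_index: float | None

    def as_row(self) -> dict:
        return {
            "label": self.label,
            "N": self.n,
            "Na": self.na,
            "Ne": self.ne,
            "I": self.shannon_i,
            "Ho": self.ho,
            "He": self.he,
            "uHe": self.uhe,
            "F": self.fixation_index,
        }


def diversity_summary(counts: GenotypeCounts) -> DiversitySummary:
    """Compute the full diversity panel for one group of genotype counts."""
    if counts.n < 1:
        raise ValueError(f"group {counts.label!r}: N must be >= 1")
    n = counts.n
    freqs = allele_frequencies(counts)
    p, q = freqs.p, freqs.q

    na = (p > 0.0) + (q > 0.0)
    sum_sq = p * p + q * q
    ne = 1.0 / sum_sq
    shannon = -sum(f * math.log(f) for f in (p, q) if f > 0.0)
    ho = counts.n12 / n
    he = 1.0 - sum_sq  # = 2pq for two alleles
    uhe = he * (2 * n) / (2 * n - 1) if n > 0 else 0.0
    fix = 1.0 - ho / he if he > 0.0 else None

    return DiversitySummary(
        label=counts.label, n=n, na=na, ne=ne, shannon_i=shannon,
        ho=ho, he=he, uhe=uhe, fixation_index=fix,
    )


def pooled_summary(counts_list: Sequence[GenotypeCounts],
                   label: str = "all") -> DiversitySummary:
    """Diversity panel of the componentwise-pooled counts.

    The groups' genotype tallies are summed first and the indices computed
    once on the pooled counts — this is *not* the mean of per-group indices
    (pooling weights every individual equally and captures between-group
    allele-frequency spread in He).
    """
    if not counts_list:
        raise ValueError("counts_list must be non-empty")
    total = reduce(lambda a, b: a + b, counts_list).relabel(label)
    return diversity_summary(total)
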