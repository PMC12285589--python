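"""Between-population differentiation: pairwise Fst, Nei distance, matrices.

Pairwise Fst uses Nei's Gst form with the *unweighted* mean of the two
populations' allele frequencies:

    p_bar = (p_a + p_b) / 2
    Ht    = 1 - sum(p_bar_i^2)          total gene diversity
    Hs    = (He_a + He_b) / 2           mean within-population diversity
    Fst   = (Ht - Hs) / Ht

Nei's unbiased genetic distance corrects the within-population
homozygosities for sample size:

    J_x  = sum(p_{a,i}^2),  uJ_x = (2N_a J_x - 1) / (2N_a - 1)
    I_N  = J_xy / sqrt(uJ_x uJ_y),  D = -ln(I_N)

Small negative residues of either measure (sampling noise, I_N slightly
above 1) are clamped to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .genotype_io import GenotypeCounts
from .locus_stats import allele_frequencies

__all__ = [
    "PairwiseResult",
    "PairMatrix",
    "pairwise_fst",
    "nei_unbiased_distance",
    "pairwise_result",
    "build_pair_matrix",
    "overall_differentiation",
]

OVERALL_METHODS = ("unweighted", "size_weighted", "mean_pairwise")


@dataclass(frozen=True)
class PairwiseResult:
    """Fst and unbiased Nei distance for one pair, with diagnostics.

    The intermediates (Ht, Hs for Fst; Jxy and the unbiased homozygosities
    uJx/uJy for the distance) are retained for inspection.
    """

    label_a: str
    label_b: str
    fst: float
    nei_unbiased_d: float
    ht: float
    hs: float
    jxy: float
    ujx: float
    ujy: float


@dataclass(frozen=True)
class PairMatrix:
    """Labeled square matrix: Nei distance below, Fst above the diagonal."""

    labels: tuple[str, ...]
    nei: dict[tuple[str, str], float]
    fst: dict[tuple[str, str], float]

    def _pair(self, a: str, b: str) -> tuple[str, str]:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return (a, b) if ia < ib else (b, a)

    def get_fst(self, a: str, b: str) -> float:
        return 0.0 if a == b else self.fst[self._pair(a, b)]

    def get_nei(self, a: str, b: str) -> float:
        return 0.0 if a == b else self.nei[self._pair(a, b)]

    def render(self, places: int = 3, diagonal: str = "–") -> str:
        """Tab-delimited dual-triangle table: Nei lower, Fst upper."""
        from .report import round_report

        lines = ["\t".join(["label", *self.labels])]
        for i, a in enumerate(self.labels):
            cells = []
            for j, b in enumerate(self.labels):
                if i == j:
                    cells.append(diagonal)
                elif i < j:
                    cells.append(round_report(self.get_fst(a, b), places))
                else:
                    cells.append(round_report(self.get_nei(a, b), places))
            lines.append("\t".join([a, *cells]))
        return "\n".join(lines) + "\n"


def _freq_he(counts: GenotypeCounts) -> tuple[float, float]:
    p = allele_frequencies(counts).p
    return p, 2.0 * p * (1.0 - p)


def pairwise_fst(counts_a: GenotypeCounts, counts_b: GenotypeCounts) -> float:
    """Pairwise Fst (Gst form, unweighted mean allele frequency).

    Returns 0 when both populations are fixed for the same allele (Ht = 0).
    Negative floating residues are clamped to 0.
    """
    pa, he_a = _freq_he(counts_a)
    pb, he_b = _freq_he(counts_b)
    p_bar = (pa + pb) / 2.0
    ht = 2.0 * p_bar * (1.0 - p_bar)
    if ht == 0.0:
        return 0.0
    hs = (he_a + he_b) / 2.0
    return max((ht - hs) / ht, 0.0)


def nei_unbiased_distance(counts_a: GenotypeCounts,
                          counts_b: GenotypeCounts) -> float:
    """Nei's unbiased genetic distance D = -ln(Jxy / sqrt(uJx * uJy)).

    Requires at least one diploid individual per population (2N >= 2, so the
    unbiased correction (2N J - 1)/(2N - 1) is defined).  A genetic identity
    above 1 — possible at small distance because the corrections are applied
    to the within terms only — is clamped to D = 0.
    """
    return pairwise_result(counts_a, counts_b).nei_unbiased_d


def pairwise_result(counts_a: GenotypeCounts,
                    counts_b: GenotypeCounts) -> PairwiseResult:
    """Fst, Nei unbiased distance and their intermediates for one pair."""
    for c in (counts_a, counts_b):
        if c.n < 1:
            raise ValueError(f"group {c.label!r}: N must be >= 1")

    pa, he_a = _freq_he(counts_a)
    pb, he_b = _freq_he(counts_b)

    # Fst (Gst form, unweighted mean frequency)
    p_bar = (pa + pb) / 2.0
    ht = 2.0 * p_bar * (1.0 - p_bar)
    hs = (he_a + he_b) / 2.0
    fst = max((ht - hs) / ht, 0.0) if ht > 0.0 else 0.0

    # Nei unbiased distance
    jx = pa * pa + (1.0 - pa) ** 2
    jy = pb * pb + (1.0 - pb) ** 2
    jxy = pa * pb + (1.0 - pa) * (1.0 - pb)
    two_na, two_nb = 2 * counts_a.n, 2 * counts_b.n
    if two_na < 2 or two_nb < 2:
        raise ValueError("unbiased correction needs 2N >= 2 in both groups")
    ujx = (two_na * jx - 1.0) / (two_na - 1.0)
    ujy = (two_nb * jy - 1.0) / (two_nb - 1.0)
    if ujx * ujy <= 0.0:
        # a single heterozygote gives uJ = 0; the identity diverges upward,
        # so the clamped distance is 0
        dist = 0.0
        identity = math.inf
    else:
        identity = jxy / math.sqrt(ujx * ujy)
        dist = 0.0 if identity >= 1.0 else -math.log(identity)

    return PairwiseResult(
        label_a=counts_a.label, label_b=counts_b.label,
        fst=fst, nei_unbiased_d=dist,
        ht=ht, hs=hs, jxy=jxy, ujx=ujx, ujy=ujy,
    )


def build_pair_matrix(counts_list: Sequence[GenotypeCounts]) -> PairMatrix:
    """All-pairs matrix in input order: Nei below the diagonal, Fst above."""
    if len(counts_list) < 2:
        raise ValueError("need at least two groups")
    labels = tuple(c.label for c in counts_list)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels in {labels}")

    nei: dict[tuple[str, str], float] = {}
    fst: dict[tuple[str, str], float] = {}
    for i, a in enumerate(counts_list):
        for b in counts_list[i + 1:]:
            res = pairwise_result(a, b)
            nei[(a.label, b.label)] = res.nei_unbiased_d
            fst[(a.label, b.label)] = res.fst
    return PairMatrix(labels=labels, nei=nei, fst=fst)


def overall_differentiation(counts_list: Sequence[GenotypeCounts],
                            method: str = "unweighted") -> tuple[float, str]:
    """Among-population differentiation over k >= 2 groups, with method tag.

    ``unweighted``
        Gst with p_bar the plain mean of per-population frequencies and Hs
        the plain mean of per-population He.
    ``size_weighted``
        Ht from the pooled (2N-weighted) frequency, Hs the 2N-weighted mean
        of per-population He.
    ``mean_pairwise``
        Mean of the C(k, 2) pairwise Fst values.

    Returns ``(value, method)``.
    """
    if len(counts_list) < 2:
        raise ValueError("need at least two groups")
    if method not in OVERALL_METHODS:
        raise ValueError(f"method must be one of {OVERALL_METHODS}, got {method!r}")

    if method == "mean_pairwise":
        vals = [pairwise_fst(a, b)
                for i, a in enumerate(counts_list) for b in counts_list[i + 1:]]
        return sum(vals) / len(vals), method

    ps = [allele_frequencies(c).p for c in counts_list]
    hes = [2.0 * p * (1.0 - p) for p in ps]
    if method == "unweighted":
        p_bar = sum(ps) / len(ps)
        hs = sum(hes) / len(hes)
    else:  # size_weighted
        weights = [2 * c.n for c in counts_list]
        tot = sum(weights)
        p_bar = sum(p * w for p, w in zip(ps, weights)) / tot
        hs = sum(h * w for h, w in zip(hes, weights)) / tot
    ht = 2.0 * p_bar * (1.0 - p_bar)
    if ht == 0.0:
        return 0.0, method
    return max((ht - hs) / ht, 0.0), method
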