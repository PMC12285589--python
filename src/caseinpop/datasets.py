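"""Built-in example data: the Ecuadorian dairy cattle A1/A2 survey.

Genotype tallies at the beta-casein (CSN2) A1/A2 locus for 1,599 animals from
five dairy cattle breeds sampled across two Ecuadorian regions (Highlands and
Coast).  The per-breed and per-region tallies are published summary counts;
the breed-by-region cross-tabulation was not published, so breed and region
tables are provided separately and cannot be joined.
"""

from __future__ import annotations

from .genotype_io import GenotypeCounts

__all__ = ["ecuador_breed_counts", "ecuador_region_counts", "ecuador_pooled_counts"]

_BREEDS = (
    ("Brown Swiss", 26, 112, 92),
    ("Cross-Bred", 48, 135, 141),
    ("Gyr", 0, 75, 183),
    ("Holstein Friesian", 98, 325, 278),
    ("Jersey", 4, 39, 43),
)

_REGIONS = (
    ("Highlands", 161, 543, 495),
    ("Coast", 15, 143, 242),
)


def ecuador_breed_counts() -> list[GenotypeCounts]:
    """Per-breed (A1A1, A1A2, A2A2) tallies, alphabetical breed order."""
    return [GenotypeCounts(label, n11, n12, n22) for label, n11, n12, n22 in _BREEDS]


def ecuador_region_counts() -> list[GenotypeCounts]:
    """Per-region tallies (Highlands n=1,199; Coast n=400)."""
    return [GenotypeCounts(label, n11, n12, n22) for label, n11, n12, n22 in _REGIONS]


def ecuador_pooled_counts() -> GenotypeCounts:
    """All 1,599 animals pooled."""
    total = [sum(col) for col in zip(*(row[1:] for row in _BREEDS))]
    return GenotypeCounts("All Breeds", *total)
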