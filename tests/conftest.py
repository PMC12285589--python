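"""Shared fixtures: the Ecuadorian study counts and its printed summaries."""

import pytest

from caseinpop.datasets import (
    ecuador_breed_counts,
    ecuador_pooled_counts,
    ecuador_region_counts,
)


@pytest.fixture(scope="session")
def breed_counts():
    """Per-breed genotype tallies (five breeds, alphabetical)."""
    return ecuador_breed_counts()


@pytest.fixture(scope="session")
def region_counts():
    return ecuador_region_counts()


@pytest.fixture(scope="session")
def all_group_counts(breed_counts, region_counts):
    """Breeds + pooled + regions, the eight published summary groups."""
    return breed_counts + [ecuador_pooled_counts()] + region_counts


#: Published allele frequencies (A1), 3 d.p., same order as all_group_counts.
PUBLISHED_A1_FREQ = {
    "Brown Swiss": 0.357,
    "Cross-Bred": 0.356,
    "Gyr": 0.145,
    "Holstein Friesian": 0.372,
    "Jersey": 0.273,
    "All Breeds": 0.325,
    "Highlands": 0.361,
    "Coast": 0.216,
}

#: Published Hardy-Weinberg p-values, 3 d.p.
PUBLISHED_HWE_P = {
    "Brown Swiss": 0.353,
    "Cross-Bred": 0.098,
    "Gyr": 0.006,
    "Holstein Friesian": 0.847,
    "Jersey": 0.189,
    "All Breeds": 0.389,
    "Highlands": 0.532,
    "Coast": 0.274,
}

#: Published HWE expected genotype counts (rounded intermediates upstream,
#: hence compared with |delta| <= 0.05).
PUBLISHED_EXPECTED_COUNTS = {
    "Brown Swiss": (29.22, 105.54, 95.22),
    "Cross-Bred": (41.17, 148.65, 134.17),
    "Gyr": (5.45, 64.09, 188.45),
    "Holstein Friesian": (96.80, 327.39, 276.81),
    "Jersey": (6.42, 34.16, 45.42),
    "All Breeds": (168.46, 701.09, 729.46),
    "Highlands": (156.01, 552.98, 490.01),
    "Coast": (18.70, 135.58, 245.70),
}

#: Published diversity panel (N, Na, Ne, I, Ho, He, uHe, F) at 3 d.p.
#: Two cells are known typographical artifacts of the source table and are
#: checked at a loosened tolerance instead of exact rendering:
#: Holstein Friesian Ne (printed 1.877, full precision 1.876) and Jersey uHe
#: (printed 0.397 = its He, full precision 0.399).
PUBLISHED_DIVERSITY = {
    "Brown Swiss": (230, 2, 1.848, 0.651, 0.487, 0.459, 0.460, -0.061),
    "Cross-Bred": (324, 2, 1.848, 0.651, 0.417, 0.459, 0.460, 0.092),
    "Gyr": (258, 2, 1.331, 0.415, 0.291, 0.248, 0.249, -0.170),
    "Holstein Friesian": (701, 2, 1.877, 0.660, 0.464, 0.467, 0.467, 0.007),
    "Jersey": (86, 2, 1.659, 0.586, 0.453, 0.397, 0.397, -0.142),
    "All Breeds": (1599, 2, 1.781, 0.630, 0.429, 0.438, 0.439, 0.022),
    "Highlands": (1199, 2, 1.856, 0.654, 0.453, 0.461, 0.461, 0.018),
    "Coast": (400, 2, 1.513, 0.522, 0.358, 0.339, 0.339, -0.055),
}
DIVERSITY_ARTIFACT_CELLS = {("Holstein Friesian", "Ne"), ("Jersey", "uHe")}

#: Published pairwise Fst (upper triangle), 3 d.p., keys in breed order.
PUBLISHED_FST = {
    ("Brown Swiss", "Cross-Bred"): 0.000,
    ("Brown Swiss", "Gyr"): 0.059,
    ("Brown Swiss", "Holstein Friesian"): 0.000,
    ("Brown Swiss", "Jersey"): 0.008,
    ("Cross-Bred", "Gyr"): 0.059,
    ("Cross-Bred", "Holstein Friesian"): 0.000,
    ("Cross-Bred", "Jersey"): 0.008,
    ("Gyr", "Holstein Friesian"): 0.067,
    ("Gyr", "Jersey"): 0.025,
    ("Holstein Friesian", "Jersey"): 0.011,
}

#: Published unbiased Nei distances (lower triangle).  Up to 0.002 off the
#: full-precision recomputation (rounded intermediates upstream), so compared
#: with |delta| <= 0.0025.
PUBLISHED_NEI = {
    ("Brown Swiss", "Cross-Bred"): 0.000,
    ("Brown Swiss", "Gyr"): 0.055,
    ("Brown Swiss", "Holstein Friesian"): 0.000,
    ("Brown Swiss", "Jersey"): 0.007,
    ("Cross-Bred", "Gyr"): 0.056,
    ("Cross-Bred", "Holstein Friesian"): 0.000,
    ("Cross-Bred", "Jersey"): 0.008,
    ("Gyr", "Holstein Friesian"): 0.067,
    ("Gyr", "Jersey"): 0.015,
    ("Holstein Friesian", "Jersey"): 0.013,
}
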