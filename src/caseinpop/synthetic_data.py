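"""Synthetic genotype cohorts under an inbreeding (fixation) model.

Each population is a single multinomial draw over the three genotype classes
with probabilities from the standard inbreeding decomposition at a biallelic
locus with A1 frequency p and inbreeding coefficient f:

    P(A1A1) = p^2 + f p q
    P(A1A2) = 2 p q (1 - f)
    P(A2A2) = q^2 + f p q

f = 0 recovers Hardy-Weinberg proportions; f = 1 removes heterozygotes; the
admissible lower bound max(-p/q, -q/p) keeps all three probabilities
non-negative.  Sampling is a single-snapshot draw — no pedigree, drift or
multi-generation dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
import yaml

from .genotype_io import (
    GENOTYPES,
    CohortDataset,
    GenotypeCounts,
    IndividualRecord,
)

__all__ = [
    "PopulationSpec",
    "CohortSpec",
    "genotype_probabilities",
    "simulate_population",
    "simulate_cohort",
    "load_cohort_spec",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of one simulated population.

    Attributes
    ----------
    label : str
        Population name.
    n : int
        Number of diploid individuals to draw.
    p : float
        True A1 allele frequency in [0, 1].
    f : float
        Inbreeding coefficient; must lie in [max(-p/q, -q/p), 1].
    region : str, optional
        Region label attached to simulated individuals.
    """

    label: str
    n: int
    p: float
    f: float = 0.0
    region: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.label!r}: n must be >= 1, got {self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"{self.label!r}: p must be in [0, 1], got {self.p}")
        q = 1.0 - self.p
        if self.p > 0.0 and q > 0.0:
            lower = max(-self.p / q, -q / self.p)
        else:
            lower = 0.0  # monomorphic: f has no effect, only f in [0, 1] sane
        if not lower - 1e-12 <= self.f <= 1.0:
            raise ValueError(
                f"{self.label!r}: f={self.f} outside admissible range "
                f"[{lower:.6g}, 1] for p={self.p}"
            )


@dataclass(frozen=True)
class CohortSpec:
    """A list of population specs plus the PRNG seed (no global RNG state)."""

    populations: tuple[PopulationSpec, ...]
    seed: int

    def __post_init__(self) -> None:
        labels = [s.label for s in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate population labels in {labels}")


def genotype_probabilities(p: float, f: float) -> tuple[float, float, float]:
    """Genotype class probabilities under the inbreeding model."""
    q = 1.0 - p
    fpq = f * p * q
    probs = (p * p + fpq, 2.0 * p * q * (1.0 - f), q * q + fpq)
    if min(probs) < -1e-12:
        raise ValueError(f"invalid (p={p}, f={f}): negative genotype probability")
    return tuple(max(x, 0.0) for x in probs)


def simulate_population(spec: PopulationSpec,
                        rng: np.random.Generator) -> GenotypeCounts:
    """Draw one population's genotype tallies from a single multinomial."""
    probs = genotype_probabilities(spec.p, spec.f)
    n11, n12, n22 = (int(x) for x in rng.multinomial(spec.n, probs))
    return GenotypeCounts(label=spec.label, n11=n11, n12=n12, n22=n22)


def simulate_cohort(spec: CohortSpec) -> CohortDataset:
    """Simulate all populations and expand them to individual records.

    Individual ids are ``<label>_<k>``; populations are drawn in spec order
    from a single :class:`numpy.random.Generator` seeded with ``spec.seed``,
    so the dataset is reproducible bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[IndividualRecord] = []
    for pop in spec.populations:
        counts = simulate_population(pop, rng)
        k = 0
        for call, n_call in zip(GENOTYPES, counts.as_tuple()):
            for _ in range(n_call):
                records.append(
                    IndividualRecord(
                        individual_id=f"{pop.label}_{k}",
                        population=pop.label,
                        region=pop.region,
                        call=call,
                    )
                )
                k += 1
    return CohortDataset(records=records, provenance=f"simulated(seed={spec.seed})")


def load_cohort_spec(source: str | IO[str]) -> CohortSpec:
    """Read a :class:`CohortSpec` from YAML/JSON.

    Layout::

        seed: 42
        populations:
          - {label: A, n: 100, p: 0.3, f: 0.0, region: north}
          - {label: B, n: 200, p: 0.7}
    """
    if hasattr(source, "read"):
        payload = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "populations" not in payload:
        raise ValueError("cohort spec must be a mapping with a 'populations' list")
    pops = tuple(
        PopulationSpec(
            label=str(entry["label"]),
            n=int(entry["n"]),
            p=float(entry["p"]),
            f=float(entry.get("f", 0.0)),
            region=entry.get("region"),
        )
        for entry in payload["populations"]
    )
    return CohortSpec(populations=pops, seed=int(payload.get("seed", 0)))
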