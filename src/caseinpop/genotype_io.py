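"""Reading, validating and tallying A1/A2 genotype data.

Two input layouts are supported:

* an *individual table* — one row per animal with an id, a population label,
  an optional region label and a genotype call (``A1A1``, ``A1A2``, ``A2A2``);
* a *count table* — one row per group with the three genotype tallies already
  summed (``label, n_A1A1, n_A1A2, n_A2A2``), the form in which published
  studies usually print their data.

All downstream statistics operate on :class:`GenotypeCounts`, so the two
layouts converge immediately after parsing.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenotypeCounts",
    "IndividualRecord",
    "CohortDataset",
    "GenotypeValidationError",
    "normalize_call",
    "read_individual_table",
    "read_count_table",
    "write_count_table",
    "tally",
]

logger = logging.getLogger(__name__)

#: Canonical genotype codes at the biallelic locus.
HOM_A1 = "A1A1"
HET = "A1A2"
HOM_A2 = "A2A2"
GENOTYPES = (HOM_A1, HET, HOM_A2)

#: Tokens treated as a missing call by default (case-insensitive).
DEFAULT_MISSING = ("", "na", "nan", ".")


class GenotypeValidationError(ValueError):
    """Raised when an input table violates the genotype-data contract."""


def normalize_call(token: str, missing: Sequence[str] = DEFAULT_MISSING) -> str | None:
    """Normalize a genotype token to one of ``A1A1``/``A1A2``/``A2A2``.

    Matching is case-insensitive and the heterozygote is unordered
    (``a2a1`` -> ``A1A2``).  Tokens in *missing* map to ``None``.
    Anything else raises :class:`GenotypeValidationError`.
    """
    t = token.strip().lower()
    if t in (m.lower() for m in missing):
        return None
    if t == "a1a1":
        return HOM_A1
    if t in ("a1a2", "a2a1"):
        return HET
    if t == "a2a2":
        return HOM_A2
    raise GenotypeValidationError(f"unknown genotype token {token!r}")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies for one group at the A1/A2 locus.

    Attributes
    ----------
    label : str
        Group name (breed, region, or "all").
    n11, n12, n22 : int
        Counts of A1A1, A1A2 and A2A2 individuals.
    """

    label: str
    n11: int
    n12: int
    n22: int

    def __post_init__(self) -> None:
        for name in ("n11", "n12", "n22"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise GenotypeValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise GenotypeValidationError(f"{name} must be non-negative, got {v}")

    @property
    def n(self) -> int:
        """Number of genotyped individuals in the group."""
        return self.n11 + self.n12 + self.n22

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n11, self.n12, self.n22)

    def relabel(self, label: str) -> "GenotypeCounts":
        return replace(self, label=label)

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            label=self.label if self.label == other.label else "pooled",
            n11=self.n11 + other.n11,
            n12=self.n12 + other.n12,
            n22=self.n22 + other.n22,
        )


@dataclass(frozen=True)
class IndividualRecord:
    """One genotyped animal: id, population, optional region, genotype call."""

    individual_id: str
    population: str
    call: str | None
    region: str | None = None


@dataclass
class CohortDataset:
    """An ordered collection of :class:`IndividualRecord` with provenance."""

    records: list[IndividualRecord] = field(default_factory=list)
    provenance: str = "<unknown>"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [r.individual_id for r in self.records],
                "population": [r.population for r in self.records],
                "region": [r.region for r in self.records],
                "genotype": [r.call for r in self.records],
            }
        )


def _detect_delimiter(text: str) -> str:
    header = text.splitlines()[0] if text else ""
    return "\t" if "\t" in header else ","


def _as_text(source: str | IO[str]) -> tuple[str, str]:
    """Return (text, provenance) from a path or open text stream."""
    if hasattr(source, "read"):
        return source.read(), getattr(source, "name", "<stream>")
    with open(source, "r", encoding="utf-8") as fh:
        return fh.read(), str(source)


def read_individual_table(
    source: str | IO[str],
    *,
    delimiter: str | None = None,
    columns: Mapping[str, str] | None = None,
    missing: Sequence[str] = DEFAULT_MISSING,
) -> CohortDataset:
    """Read a per-individual genotype table into a :class:`CohortDataset`.

    Parameters
    ----------
    source
        Path or open text stream of delimited text with a header row.
    delimiter
        Field separator; auto-detected between comma and tab when ``None``.
    columns
        Optional mapping from the logical names ``individual_id``,
        ``population``, ``region``, ``genotype`` to the file's column names.
    missing
        Tokens (case-insensitive) that mark a missing genotype call.

    Raises
    ------
    GenotypeValidationError
        On a duplicate individual id, an unknown genotype token (with the
        offending row and token named), or a missing required column.
    """
    text, provenance = _as_text(source)
    sep = delimiter or _detect_delimiter(text)
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)

    names = {"individual_id": "individual_id", "population": "population",
             "region": "region", "genotype": "genotype"}
    if columns:
        names.update(columns)
    for logical in ("individual_id", "population", "genotype"):
        if names[logical] not in df.columns:
            raise GenotypeValidationError(
                f"required column {names[logical]!r} not found in {provenance}"
            )
    has_region = names["region"] in df.columns

    records: list[IndividualRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        iid = str(row[names["individual_id"]]).strip()
        if not iid:
            raise GenotypeValidationError(f"empty individual_id at row {idx}")
        if iid in seen:
            raise GenotypeValidationError(f"duplicate individual_id {iid!r} at row {idx}")
        seen.add(iid)
        try:
            call = normalize_call(str(row[names["genotype"]]), missing=missing)
        except GenotypeValidationError as exc:
            raise GenotypeValidationError(f"row {idx}: {exc}") from None
        region = str(row[names["region"]]).strip() if has_region else ""
        records.append(
            IndividualRecord(
                individual_id=iid,
                population=str(row[names["population"]]).strip(),
                region=region or None,
                call=call,
            )
        )
    return CohortDataset(records=records, provenance=provenance)


def read_count_table(
    source: str | IO[str],
    *,
    delimiter: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> list[GenotypeCounts]:
    """Read a pre-tallied genotype-count table.

    Expected columns (remappable via *columns*): ``label``, ``n_A1A1``,
    ``n_A1A2``, ``n_A2A2``.  Thousands separators inside quoted fields are
    tolerated.  The group total N is always recomputed from the three counts,
    never read from the file.
    """
    text, provenance = _as_text(source)
    sep = delimiter or _detect_delimiter(text)
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str,
                     keep_default_na=False, thousands=",")

    names = {"label": "label", "n11": "n_A1A1", "n12": "n_A1A2", "n22": "n_A2A2"}
    if columns:
        names.update(columns)
    for logical, col in names.items():
        if col not in df.columns:
            raise GenotypeValidationError(
                f"required column {col!r} not found in {provenance}"
            )

    out: list[GenotypeCounts] = []
    for idx, row in df.iterrows():
        vals = {}
        for key in ("n11", "n12", "n22"):
            raw = str(row[names[key]]).replace(",", "").strip()
            try:
                v = int(raw)
            except ValueError:
                raise GenotypeValidationError(
                    f"row {idx + 2}: count {names[key]}={raw!r} is not an integer"
                ) from None
            if v < 0:
                raise GenotypeValidationError(
                    f"row {idx + 2}: count {names[key]}={v} is negative"
                )
            vals[key] = v
        out.append(GenotypeCounts(label=str(row[names["label"]]).strip(), **vals))
    return out


def write_count_table(counts: Iterable[GenotypeCounts], dest: str | IO[str]) -> None:
    """Write a count table as CSV (the layout :func:`read_count_table` reads)."""
    df = pd.DataFrame(
        {
            "label": [c.label for c in counts],
            "n_A1A1": [c.n11 for c in counts],
            "n_A1A2": [c.n12 for c in counts],
            "n_A2A2": [c.n22 for c in counts],
        }
    )
    if hasattr(dest, "write"):
        df.to_csv(dest, index=False)
    else:
        df.to_csv(dest, index=False)


def tally(dataset: CohortDataset, grouping: str = "by_population") -> list[GenotypeCounts]:
    """Tally genotype counts per group.

    Parameters
    ----------
    dataset
        The cohort to tally.
    grouping
        One of ``by_population``, ``by_region``, ``pooled``.  Records with a
        missing call are always excluded; for ``by_region`` records with no
        region are additionally excluded with a warning.

    Group order follows first appearance in the dataset; the pooled group is
    labeled ``"all"``.
    """
    if not dataset.records:
        raise GenotypeValidationError("cannot tally an empty dataset")

    if grouping == "pooled":
        keyf = lambda r: "all"  # noqa: E731
    elif grouping == "by_population":
        keyf = lambda r: r.population  # noqa: E731
    elif grouping == "by_region":
        keyf = lambda r: r.region  # noqa: E731
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    order: list[str] = []
    acc: dict[str, list[int]] = {}
    n_skipped_region = 0
    for rec in dataset.records:
        if rec.call is None:
            continue
        key = keyf(rec)
        if key is None:
            n_skipped_region += 1
            continue
        if key not in acc:
            acc[key] = [0, 0, 0]
            order.append(key)
        acc[key][GENOTYPES.index(rec.call)] += 1
    if n_skipped_region:
        msg = f"{n_skipped_region} record(s) without a region excluded from by_region tally"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return [GenotypeCounts(label=k, n11=acc[k][0], n12=acc[k][1], n22=acc[k][2])
            for k in order]
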