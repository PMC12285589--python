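"""Pipeline orchestration and report rendering.

Runs the full analysis (read -> tally -> frequencies, HWE, diversity,
differentiation) and writes four delimited reports plus one JSON payload of
full-precision values.  All table cells are rendered with half-up decimal
rounding; statistics are always computed at full precision and rounded only
at the rendering boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import __version__
from .differentiation import build_pair_matrix, overall_differentiation
from .diversity import diversity_summary
from .genotype_io import (
    GenotypeCounts,
    GenotypeValidationError,
    read_count_table,
    read_individual_table,
    tally,
)
from .locus_stats import allele_frequencies, genotype_frequencies, hwe_test

__all__ = ["PipelineConfig", "RunReport", "round_report", "run_pipeline"]

logger = logging.getLogger(__name__)

GROUPINGS = ("by_population", "by_region", "pooled")
LAYOUTS = ("individuals", "counts")


def round_report(value: float | None, places: int) -> str:
    """Render *value* as a decimal string with half-up rounding.

    Ties round away from zero (0.3575 at 3 places -> "0.358"); ``None`` and
    NaN render as "NA".
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    quantum = Decimal(1).scaleb(-places)
    return str(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    input_path: str
    layout: str = "counts"
    groupings: tuple[str, ...] = ("by_population",)
    out_dir: str = "."
    places: int = 3            # index / p-value precision
    freq_places: int = 2       # genotype-frequency display precision
    overall_method: str = "unweighted"

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}, got {self.layout!r}")
        bad = [g for g in self.groupings if g not in GROUPINGS]
        if bad:
            raise ValueError(f"unknown grouping(s) {bad}; choose from {GROUPINGS}")
        if not self.groupings:
            raise ValueError("at least one grouping must be requested")


@dataclass
class RunReport:
    """In-memory result of a pipeline run (full precision)."""

    groups: dict[str, list[GenotypeCounts]]
    payload: dict
    warnings: list[str] = field(default_factory=list)
    version: str = __version__
    input_digest: str = ""


def _read_groups(config: PipelineConfig) -> dict[str, list[GenotypeCounts]]:
    path = config.input_path
    groups: dict[str, list[GenotypeCounts]] = {}
    if config.layout == "individuals":
        dataset = read_individual_table(path)
        if not dataset.records:
            raise GenotypeValidationError(f"no records in {path}")
        for g in config.groupings:
            groups[g] = tally(dataset, g)
    else:
        rows = read_count_table(path)
        if not rows:
            raise GenotypeValidationError(f"no rows in {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for g in config.groupings:
            if g == "by_population":
                groups[g] = rows
            elif g == "pooled":
                total = rows[0]
                for r in rows[1:]:
                    total = total + r
                groups[g] = [total.relabel("all")]
            else:  # by_region: aggregate rows sharing a region, if present
                if "region" not in df.columns:
                    logger.warning("count table has no region column; "
                                   "by_region grouping skipped")
                    continue
                acc: dict[str, GenotypeCounts] = {}
                order: list[str] = []
                for row, counts in zip(df.itertuples(index=False), rows):
                    region = str(getattr(row, "region", "")).strip()
                    if not region:
                        continue
                    if region in acc:
                        acc[region] = (acc[region] + counts).relabel(region)
                    else:
                        acc[region] = counts.relabel(region)
                        order.append(region)
                groups[g] = [acc[r] for r in order]
    return {g: v for g, v in groups.items() if v}


def _genotype_table(counts_list: list[GenotypeCounts], config: PipelineConfig,
                    warnings_out: list[str]) -> pd.DataFrame:
    rows = []
    for c in counts_list:
        summ = genotype_frequencies(c)
        hwe = hwe_test(c)
        if hwe.low_expected:
            warnings_out.append(
                f"{c.label}: an expected genotype count is below 5; "
                "chi-square approximation may be fragile"
            )
        fp = config.freq_places
        rows.append({
            "label": c.label, "row": "Observed",
            "A1A1": f"{round_report(summ.observed_freqs[0], fp)} ({c.n11})",
            "A1A2": f"{round_report(summ.observed_freqs[1], fp)} ({c.n12})",
            "A2A2": f"{round_report(summ.observed_freqs[2], fp)} ({c.n22})",
            "p": round_report(hwe.p_value, config.places),
        })
        e11, e12, e22 = hwe.expected_counts
        f11, f12, f22 = hwe.expected_freqs
        rows.append({
            "label": c.label, "row": "Expected",
            "A1A1": f"{round_report(f11, fp)} ({round_report(e11, 2)})",
            "A1A2": f"{round_report(f12, fp)} ({round_report(e12, 2)})",
            "A2A2": f"{round_report(f22, fp)} ({round_report(e22, 2)})",
            "p": "",
        })
    return pd.DataFrame(rows)


def _allele_table(counts_list: list[GenotypeCounts],
                  config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for c in counts_list:
        freqs = allele_frequencies(c)
        rows.append({
            "label": c.label,
            "A1": round_report(freqs.p, config.places),
            "A2": round_report(freqs.q, config.places),
        })
    return pd.DataFrame(rows)


def _diversity_table(counts_list: list[GenotypeCounts],
                     config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for c in counts_list:
        d = diversity_summary(c)
        rows.append({
            "label": d.label, "N": d.n,
            "Na": round_report(float(d.na), config.places),
            "Ne": round_report(d.ne, config.places),
            "I": round_report(d.shannon_i, config.places),
            "Ho": round_report(d.ho, config.places),
            "He": round_report(d.he, config.places),
            "uHe": round_report(d.uhe, config.places),
            "F": round_report(d.fixation_index, config.places),
        })
    return pd.DataFrame(rows)


def _full_precision_payload(groups: dict[str, list[GenotypeCounts]],
                            config: PipelineConfig) -> dict:
    payload: dict = {"groupings": {}}
    for g, counts_list in groups.items():
        entries = []
        for c in counts_list:
            freqs = allele_frequencies(c)
            hwe = hwe_test(c)
            d = diversity_summary(c)
            entries.append({
                "label": c.label,
                "counts": {"A1A1": c.n11, "A1A2": c.n12, "A2A2": c.n22, "N": c.n},
                "allele_freqs": {"A1": freqs.p, "A2": freqs.q},
                "hwe": {
                    "expected_counts": list(hwe.expected_counts),
                    "chi_square": hwe.chi_square,
                    "df": hwe.df,
                    "p_value": hwe.p_value,
                    "valid": hwe.valid,
                    "low_expected": hwe.low_expected,
                },
                "diversity": {
                    "Na": d.na, "Ne": d.ne, "I": d.shannon_i, "Ho": d.ho,
                    "He": d.he, "uHe": d.uhe, "F": d.fixation_index,
                },
            })
        payload["groupings"][g] = entries

    pops = groups.get("by_population", [])
    if len(pops) >= 2:
        matrix = build_pair_matrix(pops)
        payload["differentiation"] = {
            "labels": list(matrix.labels),
            "fst": {f"{a}|{b}": v for (a, b), v in matrix.fst.items()},
            "nei_unbiased_d": {f"{a}|{b}": v for (a, b), v in matrix.nei.items()},
        }
        value, tag = overall_differentiation(pops, config.overall_method)
        payload["overall_differentiation"] = {"value": value, "method": tag}
    return payload


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and write reports under ``config.out_dir``.

    Outputs: ``genotype_frequencies.csv``, ``allele_frequencies.csv``,
    ``diversity_indices.csv``, ``differentiation_matrix.tsv`` (when at least
    two populations are present) and ``results.json`` with full-precision
    values.  All computation happens before any file is written, so a
    validation error leaves no partial outputs.
    """
    groups = _read_groups(config)
    if not groups:
        raise GenotypeValidationError("no grouping produced any data")

    warnings_out: list[str] = []
    all_counts = [c for g in config.groupings if g in groups for c in groups[g]]
    genotype_df = _genotype_table(all_counts, config, warnings_out)
    allele_df = _allele_table(all_counts, config)
    diversity_df = _diversity_table(all_counts, config)
    payload = _full_precision_payload(groups, config)

    pops = groups.get("by_population", [])
    matrix_text = build_pair_matrix(pops).render(config.places) if len(pops) >= 2 else None

    digest = hashlib.sha256(Path(config.input_path).read_bytes()).hexdigest()
    payload["version"] = __version__
    payload["input_digest"] = digest
    payload["warnings"] = warnings_out

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotype_df.to_csv(out / "genotype_frequencies.csv", index=False)
    allele_df.to_csv(out / "allele_frequencies.csv", index=False)
    diversity_df.to_csv(out / "diversity_indices.csv", index=False)
    if matrix_text is not None:
        (out / "differentiation_matrix.tsv").write_text(matrix_text, encoding="utf-8")
    with open(out / "results.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)

    for g, counts_list in groups.items():
        logger.info("%s: %d group(s), N = %s", g, len(counts_list),
                    [c.n for c in counts_list])
    for w in warnings_out:
        logger.warning(w)

    return RunReport(groups=groups, payload=payload, warnings=warnings_out,
                     version=__version__, input_digest=digest)
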