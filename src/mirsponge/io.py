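"""Delimited-table readers and construct report writers.

Screen tables are CSV or TSV (delimiter sniffed) with these columns:

- viability: ``line_id, n_experimental, n_control[, batch]``
- flight: ``line_id, age_days, replicate, n_total, n_inner, n_middle,
  n_outer, n_target_miss``
- benchmark: ``gene_id, sponge_phenotype, null_exists[, null_phenotype,
  cluster_deletion, validated, family_id]``

Construct outputs are a single-record cassette FASTA, a BED-like block
TSV (0-based half-open: kind, start, end, name) and a JSON design
report echoing the configuration, chosen linkers and warnings.
"""

from __future__ import annotations

from dataclasses import asdict
from os import PathLike
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import Cassette, DesignConfig
from .errors import ScreenInputError
from .screen import (BenchmarkEntry, FlightTrial, ViabilityRecord,
                     percent_viability)

__all__ = [
    "read_table",
    "read_viability_table",
    "read_flight_table",
    "read_benchmark_table",
    "viability_percent_table",
    "flight_fraction_table",
    "records_to_frame",
    "cassette_to_fasta",
    "blocks_to_tsv",
    "design_report",
]

_BOOL_STRINGS = {"true": True, "1": True, "yes": True,
                 "false": False, "0": False, "no": False}


def read_table(path: str | PathLike) -> pd.DataFrame:
    """Read a CSV/TSV with delimiter sniffing."""
    return pd.read_csv(path, sep=None, engine="python")


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ScreenInputError(
            f"{what} table missing columns: {', '.join(missing)}")


def _as_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return value
    try:
        return bool(_BOOL_STRINGS[str(value).strip().lower()])
    except KeyError:
        raise ScreenInputError(f"cannot parse boolean {value!r}") from None


def read_viability_table(path: str | PathLike) -> list[ViabilityRecord]:
    df = read_table(path)
    _require(df, ["line_id", "n_experimental", "n_control"], "viability")
    return [ViabilityRecord(str(r.line_id), int(r.n_experimental),
                            int(r.n_control),
                            str(r.batch) if "batch" in df.columns else None)
            for r in df.itertuples()]


def read_flight_table(path: str | PathLike) -> list[FlightTrial]:
    df = read_table(path)
    _require(df, ["line_id", "age_days", "replicate", "n_total", "n_inner",
                  "n_middle", "n_outer", "n_target_miss"], "flight")
    return [FlightTrial(str(r.line_id), int(r.age_days), str(r.replicate),
                        int(r.n_total), int(r.n_inner), int(r.n_middle),
                        int(r.n_outer), int(r.n_target_miss))
            for r in df.itertuples()]


def read_benchmark_table(path: str | PathLike) -> list[BenchmarkEntry]:
    df = read_table(path)
    _require(df, ["gene_id", "sponge_phenotype", "null_exists"], "benchmark")
    entries = []
    for r in df.itertuples():
        family = getattr(r, "family_id", None)
        if pd.isna(family):
            family = None
        entries.append(BenchmarkEntry(
            str(r.gene_id), str(r.sponge_phenotype),
            _as_bool(r.null_exists),
            str(getattr(r, "null_phenotype", "not_tested")),
            _as_bool(getattr(r, "cluster_deletion", False)),
            _as_bool(getattr(r, "validated", False)),
            str(family) if family is not None else None))
    return entries


def viability_percent_table(records: Iterable[ViabilityRecord],
                            cf: float = 1.0,
                            batch_cf: Mapping[str, float] | None = None,
                            ) -> dict[str, float]:
    """Mean percent viability per line, correction applied per record.

    ``cf`` is the global balancer correction factor; ``batch_cf`` maps
    batch labels to per-batch factors and overrides ``cf`` where a
    record's batch is listed.
    """
    sums: dict[str, list[float]] = {}
    for rec in records:
        factor = cf
        if batch_cf is not None and rec.batch in batch_cf:
            factor = batch_cf[rec.batch]
        sums.setdefault(rec.line_id, []).append(
            percent_viability(rec, factor))
    return {line: sum(v) / len(v) for line, v in sums.items()}


def flight_fraction_table(trials: Iterable[FlightTrial],
                          age_days: int | None = None,
                          ) -> dict[str, list[float]]:
    """Per-line replicate non-flier fractions, optionally one age only."""
    from .screen import nonflier_fraction
    table: dict[str, list[float]] = {}
    for trial in trials:
        if age_days is not None and trial.age_days != age_days:
            continue
        table.setdefault(trial.line_id, []).append(nonflier_fraction(trial))
    return table


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Dataclass rows (viability / flight / benchmark) to a DataFrame."""
    return pd.DataFrame([asdict(r) for r in records])


def cassette_to_fasta(cassette: Cassette, path: str | PathLike) -> None:
    name = cassette.target_id or "cassette"
    record = SeqRecord(Seq(cassette.full_seq), id=f"{name}-SP",
                       description=f"{cassette.n_repeats} sites, "
                                   f"{len(cassette.linkers)} linkers")
    SeqIO.write([record], str(path), "fasta")


def blocks_to_tsv(cassette: Cassette, path: str | PathLike) -> None:
    df = pd.DataFrame(cassette.blocks,
                      columns=["kind", "start", "end", "name"])
    df.to_csv(path, sep="\t", index=False)


def design_report(cassette: Cassette, config: DesignConfig) -> dict:
    """JSON-serialisable summary of one design run."""
    return {
        "target": cassette.target_id,
        "n_repeats": cassette.n_repeats,
        "linkers": list(cassette.linkers),
        "flank_5": cassette.flank_5,
        "flank_3": cassette.flank_3,
        "length_nt": len(cassette.full_seq),
        "config": {
            "n_repeats": config.n_repeats,
            "mismatch_span": list(config.mismatch_span),
            "linker_length": config.linker_length,
            "enabled_match_types": sorted(
                t.value for t in config.enabled_match_types),
            "flank_enzymes": [list(fe) for fe in config.flank_enzymes],
            "linker_order": config.linker_order,
            "rng_seed": config.rng_seed,
        },
        "warnings": list(cassette.warnings),
    }
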