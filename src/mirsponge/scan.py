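"""Seed-match site scanning: k-mer index, sliding-window scan, naive oracle.

Only the transcript sense strand is scanned — sponges act as RNA and
miRNA target recognition is strand-specific. Overlapping hits are all
reported without merging; a narrower hit contained in a wider hit for
the same miRNA (e.g. a 7mer-m8 inside an 8mer at the same locus) is
flagged ``nested`` rather than deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AlphabetError
from .registry import (DEFAULT_MATCH_TYPES, MatchType, MatureMiRNA, Registry,
                       seed_kmers)

__all__ = [
    "MatchType",
    "Hit",
    "SeedIndex",
    "CollisionReport",
    "build_seed_index",
    "scan_sequence",
    "naive_scan",
]

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class Hit:
    """One candidate miRNA site in a scanned sequence (0-based window)."""

    start: int
    width: int
    matched_id: str
    match_type: MatchType
    region: str = "other"
    nested: bool = False

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass(frozen=True)
class SeedIndex:
    """k-mer -> {(miRNA id, MatchType)} lookup for a registry.

    Every stored k-mer has the width of its match type, so substring
    lookup by width is automatically type-consistent. The index is
    recomputable from the registry (derived data, not a store).
    """

    kmers: Mapping[str, frozenset[tuple[str, MatchType]]]
    enabled_types: frozenset[MatchType]

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(sorted({t.width for t in self.enabled_types}))


@dataclass(frozen=True)
class CollisionReport:
    """Hits found in one scanned sequence, sorted by (start, width)."""

    hits: tuple[Hit, ...]
    scanned_length: int
    exemptions: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.hits)

    def __bool__(self) -> bool:
        return bool(self.hits)

    def in_region(self, region: str) -> tuple[Hit, ...]:
        return tuple(h for h in self.hits if h.region == region)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form used by the CLI TSV report."""
        return pd.DataFrame(
            [{"start": h.start, "end": h.end, "width": h.width,
              "miRNA": h.matched_id, "type": h.match_type.value,
              "region": h.region, "nested": h.nested} for h in self.hits],
            columns=["start", "end", "width", "miRNA", "type", "region",
                     "nested"])


def build_seed_index(registry: Registry,
                     enabled_types: Iterable[MatchType] = DEFAULT_MATCH_TYPES,
                     ) -> SeedIndex:
    """Index every enabled seed-match k-mer of every registry miRNA.

    k-mers shared by several miRNAs (family members) map to all of them.
    An empty registry yields an empty index.
    """
    enabled = frozenset(enabled_types)
    kmers: dict[str, set[tuple[str, MatchType]]] = {}
    for m in registry:
        for match_type, kmer in seed_kmers(m, enabled).items():
            kmers.setdefault(kmer, set()).add((m.id, match_type))
    return SeedIndex({k: frozenset(v) for k, v in kmers.items()}, enabled)


def _validate_dna(seq: str) -> None:
    for i, base in enumerate(seq):
        if base not in _DNA:
            raise AlphabetError(
                f"illegal DNA nucleotide {base!r} at offset {i}", offset=i)


def _region_of(start: int, end: int, region_map) -> str:
    """Label a window against a block coordinate table.

    Junction = overlaps at least one linker base; else flank if it
    touches a flank block; else site_internal if fully inside one site
    block; else other. Blocks may be objects with ``kind``/``start``/
    ``end`` attributes or (kind, start, end, ...) tuples.
    """
    touches_flank = False
    for block in region_map:
        kind, b_start, b_end = _block_fields(block)
        if b_start >= end or b_end <= start:
            continue
        if kind == "linker":
            return "junction"
        if kind == "flank":
            touches_flank = True
        if kind == "site" and b_start <= start and end <= b_end:
            # provisional; a later linker overlap would have returned above
            # only if blocks were unordered — keep scanning for linkers
            continue
    if touches_flank:
        return "flank"
    for block in region_map:
        kind, b_start, b_end = _block_fields(block)
        if kind == "site" and b_start <= start and end <= b_end:
            return "site_internal"
    return "other"


def _block_fields(block) -> tuple[str, int, int]:
    if hasattr(block, "kind"):
        return block.kind, block.start, block.end
    kind, start, end = block[0], block[1], block[2]
    return kind, start, end


def _finalise(raw: list[Hit], seq_len: int, exempt: frozenset[str],
              region_map) -> CollisionReport:
    raw.sort(key=lambda h: (h.start, h.width, h.matched_id,
                            h.match_type.value))
    out: list[Hit] = []
    for h in raw:
        region = (_region_of(h.start, h.end, region_map)
                  if region_map is not None else h.region)
        nested = any(o is not h and o.matched_id == h.matched_id
                     and o.start <= h.start and h.end <= o.end
                     and o.width > h.width for o in raw)
        out.append(replace(h, region=region, nested=nested))
    return CollisionReport(tuple(out), seq_len, exempt)


def scan_sequence(seq: str, index: SeedIndex,
                  exempt: Iterable[str] = (),
                  region_map: Sequence | None = None) -> CollisionReport:
    """Slide every enabled window width over ``seq`` and look hits up.

    Hits to exempt miRNA ids are dropped. With a ``region_map`` (a
    cassette block table) each hit is labelled junction / site_internal
    / flank / other. Sequences shorter than the smallest width yield an
    empty report.
    """
    _validate_dna(seq)
    exempt = frozenset(exempt)
    raw: list[Hit] = []
    for width in index.widths:
        for start in range(len(seq) - width + 1):
            matches = index.kmers.get(seq[start:start + width])
            if not matches:
                continue
            for mirna_id, match_type in matches:
                if mirna_id not in exempt:
                    raw.append(Hit(start, width, mirna_id, match_type))
    return _finalise(raw, len(seq), exempt, region_map)


def naive_scan(seq: str, registry: Registry,
               enabled_types: Iterable[MatchType] = DEFAULT_MATCH_TYPES,
               exempt: Iterable[str] = (),
               region_map: Sequence | None = None) -> CollisionReport:
    """Brute-force oracle: direct substring search, no index.

    Produces a report identical to :func:`scan_sequence` on the index
    built from the same registry and types; kept deliberately simple so
    it can serve as the independent reference in equivalence tests.
    """
    _validate_dna(seq)
    exempt = frozenset(exempt)
    enabled = frozenset(enabled_types)
    raw: list[Hit] = []
    for m in registry:
        if m.id in exempt:
            continue
        for match_type, kmer in seed_kmers(m, enabled).items():
            pos = seq.find(kmer)
            while pos != -1:
                raw.append(Hit(pos, len(kmer), m.id, match_type))
                pos = seq.find(kmer, pos + 1)
    return _finalise(raw, len(seq), exempt, region_map)
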