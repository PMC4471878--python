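"""Sponge construct design: bulged sites, linkers, cassettes, scrambles.

A sponge cassette is a tandem array of miRNA binding sites separated by
short linkers and flanked by restriction sites for cloning into a
reporter 3'UTR. Each binding site is the reverse complement of the
target miRNA except across a central mismatch block (default miRNA
positions 9-12) that bulges the duplex and prevents Argonaute-catalysed
slicing, so the sponge sequesters the miRNA without being destroyed.

Linkers are chosen so that no sliding window of seed-match width
(7-8 nt) spanning a linker junction matches the seed site of any other
miRNA in the registry — the junctions must not create cryptic
off-target sites — and so that no restriction flank sequence is
recreated at a junction.

Construct coordinates are 0-based half-open; miRNA positions are
1-based from the 5' end.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import DesignError, LinkerExhaustionError, ScrambleSearchError
from .registry import (DEFAULT_MATCH_TYPES, MatchType, MatureMiRNA, Registry,
                       reverse_complement)
from .scan import SeedIndex, build_seed_index, scan_sequence

__all__ = [
    "DesignConfig",
    "BindingSite",
    "Block",
    "Cassette",
    "design_bulged_site",
    "select_linker",
    "assemble_cassette",
    "legacy_assemble",
    "generate_scramble",
    "pairs_watson_crick",
    "pairs_wobble",
    "SELF_MISMATCH_TABLE",
]

#: Default flanks: NotI upstream, XbaI downstream of the site array.
DEFAULT_FLANK_ENZYMES = (("NotI", "GCGGCCGC"), ("XbaI", "TCTAGA"))

#: Site base (DNA) placed opposite each miRNA base inside the mismatch
#: block. Copying the miRNA base itself (U written as T) guarantees the
#: pair is neither Watson-Crick nor G.U wobble, for all four bases.
SELF_MISMATCH_TABLE: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "T"}

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


def pairs_watson_crick(site_base_dna: str, mirna_base_rna: str) -> bool:
    """Would this site base (transcribed to RNA) WC-pair the miRNA base?"""
    site_rna = "U" if site_base_dna == "T" else site_base_dna
    return (site_rna, mirna_base_rna) in _WC_PAIRS


def pairs_wobble(site_base_dna: str, mirna_base_rna: str) -> bool:
    """Would this site base (transcribed to RNA) G.U-wobble the miRNA base?"""
    site_rna = "U" if site_base_dna == "T" else site_base_dna
    return (site_rna, mirna_base_rna) in _WOBBLE_PAIRS


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of cassette design.

    Defaults reproduce the second-generation sponge architecture:
    20 repeats, 4-nt linkers, mismatches at miRNA positions 9-12, NotI
    and XbaI cloning flanks, and off-target screening with the 7-8 nt
    site types (7mer-A1, 7mer-m8, 8mer; the 6mer is off by default).
    """

    n_repeats: int = 20
    mismatch_span: tuple[int, int] = (9, 12)
    linker_length: int = 4
    enabled_match_types: frozenset[MatchType] = DEFAULT_MATCH_TYPES
    flank_enzymes: tuple[tuple[str, str], ...] = DEFAULT_FLANK_ENZYMES
    linker_order: str = "lexicographic"  # or "seeded_random"
    rng_seed: int = 0
    scramble_max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise DesignError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.linker_length < 0:
            raise DesignError("linker_length must be >= 0")
        if self.linker_order not in ("lexicographic", "seeded_random"):
            raise DesignError(
                f"unknown linker_order {self.linker_order!r}")
        object.__setattr__(self, "enabled_match_types",
                           frozenset(self.enabled_match_types))
        object.__setattr__(self, "flank_enzymes",
                           tuple((n, s) for n, s in self.flank_enzymes))

    @classmethod
    def from_dict(cls, raw: Mapping) -> "DesignConfig":
        """Build a config from plain YAML/JSON data."""
        kwargs = dict(raw)
        if "mismatch_span" in kwargs:
            kwargs["mismatch_span"] = tuple(kwargs["mismatch_span"])
        if "enabled_match_types" in kwargs:
            kwargs["enabled_match_types"] = frozenset(
                MatchType(t) for t in kwargs["enabled_match_types"])
        if "flank_enzymes" in kwargs:
            kwargs["flank_enzymes"] = tuple(
                (name, seq) for name, seq in kwargs["flank_enzymes"])
        return cls(**kwargs)


@dataclass(frozen=True)
class BindingSite:
    """A designed sponge binding site on the transcript sense strand.

    ``site_seq`` is DNA, 5'->3', the same length as the target miRNA.
    Site position j (1-based) pairs miRNA position L - j + 1
    (antiparallel). ``pairing`` records, per miRNA position 1..L,
    whether the designed base Watson-Crick pairs ("WC") or is a true
    mismatch ("mismatch").
    """

    target_id: str
    site_seq: str
    mismatch_span: tuple[int, int] | None
    pairing: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.site_seq)


class Block(NamedTuple):
    """One annotated segment of a cassette (0-based half-open)."""

    kind: str  # "flank" | "site" | "linker"
    start: int
    end: int
    name: str


@dataclass(frozen=True)
class Cassette:
    """An assembled sponge cassette with full coordinate bookkeeping."""

    target_id: str | None
    n_repeats: int
    sites: tuple[BindingSite, ...]
    linkers: tuple[str, ...]
    flank_5: str
    flank_3: str
    blocks: tuple[Block, ...]
    full_seq: str
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        rebuilt = "".join(self.full_seq[b.start:b.end] for b in self.blocks)
        if rebuilt != self.full_seq:
            raise DesignError("block table does not reconstruct full_seq")

    @property
    def interior(self) -> str:
        """Sequence between the flanks (the site/linker array)."""
        return self.full_seq[len(self.flank_5):
                             len(self.full_seq) - len(self.flank_3) or None]


def design_bulged_site(m: MatureMiRNA,
                       mismatch_span: tuple[int, int] = (9, 12),
                       mismatch_table: Mapping[str, str] | None = None,
                       ) -> BindingSite:
    """Reverse-complement the miRNA and plant the central mismatch block.

    ``mismatch_span`` is an inclusive 1-based interval of miRNA
    positions; a span extending past the miRNA 3' end is clipped with a
    warning. Inside the span the site base is taken from
    ``mismatch_table`` (default: the self-mismatch rule), which must
    yield neither Watson-Crick nor G.U pairing.
    """
    table = SELF_MISMATCH_TABLE if mismatch_table is None else mismatch_table
    lo, hi = mismatch_span
    if lo < 1:
        raise DesignError(f"mismatch_span start must be >= 1, got {lo}")
    length = m.length
    clipped_hi = min(hi, length)
    if clipped_hi < hi:
        warnings.warn(
            f"{m.id}: mismatch span {lo}-{hi} clipped to {lo}-{clipped_hi} "
            f"for a {length}-nt miRNA", stacklevel=2)
    span = (lo, clipped_hi) if lo <= clipped_hi else None

    site = list(reverse_complement(m.sequence, "DNA"))
    pairing = ["WC"] * length
    if span is not None:
        for pos in range(span[0], span[1] + 1):
            site[length - pos] = table[m.sequence[pos - 1]]
            pairing[pos - 1] = "mismatch"
    return BindingSite(m.id, "".join(site), span, tuple(pairing))


def _linker_candidates(config: DesignConfig, salt: int = 0) -> list[str]:
    cands = ["".join(p) for p in
             itertools.product("ACGT", repeat=config.linker_length)]
    if config.linker_order == "seeded_random":
        rng = np.random.default_rng(
            [config.rng_seed % 2**31, salt % 2**31])
        cands = [cands[i] for i in rng.permutation(len(cands))]
    return cands


def _junction_block(junction: str, linker_start: int, linker_end: int,
                    index: SeedIndex, exempt: frozenset[str],
                    config: DesignConfig) -> str | None:
    """First collision in windows overlapping the linker, or None."""
    for width in index.widths:
        first = max(0, linker_start - width + 1)
        last = min(linker_end - 1, len(junction) - width)
        for start in range(first, last + 1):
            matches = index.kmers.get(junction[start:start + width])
            if not matches:
                continue
            for mirna_id, match_type in sorted(
                    matches, key=lambda x: (x[0], x[1].value)):
                if mirna_id not in exempt:
                    return (f"{match_type.value} site of {mirna_id} at "
                            f"junction offset {start}")
    for name, site in config.flank_enzymes:
        pos = junction.find(site)
        while pos != -1:
            if pos < linker_end and pos + len(site) > linker_start:
                return f"{name} site ({site}) at junction offset {pos}"
            pos = junction.find(site, pos + 1)
    return None


def select_linker(left_context: str, right_context: str, registry: Registry,
                  exempt: Iterable[str], config: DesignConfig,
                  *, index: SeedIndex | None = None,
                  salt: int = 0) -> str:
    """First acceptable linker in the configured enumeration order.

    A candidate is acceptable when the junction string
    ``left_context + linker + right_context`` contains, in any window
    overlapping the linker, (i) no enabled seed-match k-mer of a
    non-exempt registry miRNA and (ii) no flank-enzyme recognition
    sequence. The choice is deterministic given the config (``salt``
    varies the seeded-random order per junction).

    Contexts should carry at least width-1 (7) terminal nucleotides of
    the neighbouring blocks so every junction-overlapping window is
    visible.
    """
    exempt = frozenset(exempt)
    if index is None:
        index = build_seed_index(registry, config.enabled_match_types)
    rejections: dict[str, str] = {}
    for cand in _linker_candidates(config, salt):
        junction = left_context + cand + right_context
        block = _junction_block(junction, len(left_context),
                                len(left_context) + len(cand), index,
                                exempt, config)
        if block is None:
            return cand
        rejections[cand] = block
    raise LinkerExhaustionError(rejections)


def _build_blocks(flank_5: str, flank_3: str,
                  site_seqs: Sequence[str], linkers: Sequence[str],
                  site_name: str) -> tuple[tuple[Block, ...], str]:
    blocks: list[Block] = []
    parts: list[str] = []
    pos = 0

    def push(kind: str, seq: str, name: str) -> None:
        nonlocal pos
        if seq:
            blocks.append(Block(kind, pos, pos + len(seq), name))
            parts.append(seq)
            pos += len(seq)

    push("flank", flank_5, "flank_5")
    for i, site in enumerate(site_seqs, start=1):
        push("site", site, f"{site_name}_{i}")
        if i <= len(linkers):
            push("linker", linkers[i - 1], f"linker_{i}")
    push("flank", flank_3, "flank_3")
    return tuple(blocks), "".join(parts)


def assemble_cassette(m: MatureMiRNA, registry: Registry,
                      config: DesignConfig = DesignConfig()) -> Cassette:
    """Design and assemble a full sponge cassette for one target miRNA.

    One bulged site is designed and repeated ``config.n_repeats`` times;
    the n-1 linkers are selected independently left-to-right under the
    junction collision screen. The target itself and every registry
    miRNA sharing its extended seed (family members) are exempt from
    the screen — their sites are the design's purpose, not off-targets.

    Site-internal cryptic matches and restriction sites, which are fixed
    by the target's own sequence and cannot be designed away, are
    reported in ``Cassette.warnings`` rather than raised.
    """
    site = design_bulged_site(m, config.mismatch_span)
    exempt = registry.family_of(m)
    index = build_seed_index(registry, config.enabled_match_types)

    # 7 = widest enabled window minus one; a window overlapping a linker
    # reaches at most that far into the neighbouring site.
    ctx = max(index.widths, default=8) - 1
    left_ctx, right_ctx = site.site_seq[-ctx:], site.site_seq[:ctx]
    linkers = tuple(
        select_linker(left_ctx, right_ctx, registry, exempt, config,
                      index=index, salt=i)
        for i in range(config.n_repeats - 1))

    (flank5_name, flank_5), (flank3_name, flank_3) = \
        config.flank_enzymes[0], config.flank_enzymes[-1]
    blocks, full_seq = _build_blocks(
        flank_5, flank_3, [site.site_seq] * config.n_repeats, linkers,
        f"site_{m.id}")

    notes: list[str] = []
    report = scan_sequence(full_seq, index, exempt=exempt, region_map=blocks)
    junction_hits = report.in_region("junction")
    if junction_hits:  # guaranteed impossible by select_linker
        raise DesignError(
            f"internal error: junction collisions survived linker "
            f"selection: {junction_hits}")
    for hit in report.hits:
        if hit.region != "junction":
            notes.append(
                f"cryptic {hit.match_type.value} site of {hit.matched_id} "
                f"at {hit.start} ({hit.region}); fixed by the target "
                f"sequence, not removable by design")
    interior = full_seq[len(flank_5):len(full_seq) - len(flank_3)]
    for name, enzyme_site in config.flank_enzymes:
        pos = interior.find(enzyme_site)
        if pos != -1:
            notes.append(
                f"{name} site ({enzyme_site}) inside the cassette interior "
                f"at {len(flank_5) + pos}; arises from the binding site "
                f"itself")
    return Cassette(m.id, config.n_repeats, (site,) * config.n_repeats,
                    linkers, flank_5, flank_3, blocks, full_seq,
                    tuple(notes))


def legacy_assemble(site_seq: str, linker: str, n_repeats: int) -> Cassette:
    """Fixed-linker assembly without collision screening or flanks.

    Reproduces first-generation constructs built from a synthesised
    site repeated with one constant linker (e.g. the miR-1 sponge:
    a 21-nt site with CGCG linkers, 10 repeats).
    """
    if not site_seq:
        raise DesignError("site_seq must be non-empty")
    if n_repeats < 1:
        raise DesignError(f"n_repeats must be >= 1, got {n_repeats}")
    linkers = tuple([linker] * (n_repeats - 1))
    blocks, full_seq = _build_blocks("", "", [site_seq] * n_repeats,
                                     linkers, "site")
    site = BindingSite("legacy", site_seq, None,
                       ("WC",) * len(site_seq))
    return Cassette(None, n_repeats, (site,) * n_repeats, linkers,
                    "", "", blocks, full_seq)


def generate_scramble(template_site: str, registry: Registry,
                      config: DesignConfig = DesignConfig()) -> str:
    """Composition-preserving shuffle with no seed match to any miRNA.

    Repeatedly shuffles ``template_site`` (seeded, deterministic) until
    a permutation is found in which every window of enabled seed-match
    width misses the *entire* registry — no exemptions, a scramble
    control must match nothing — and no flank recognition sequence
    occurs. Raises after ``config.scramble_max_attempts`` shuffles,
    reporting the best candidate seen.
    """
    if not template_site:
        raise DesignError("template_site must be non-empty")
    index = build_seed_index(registry, config.enabled_match_types)
    rng = np.random.default_rng(config.rng_seed % 2**31)
    chars = np.array(list(template_site))
    best: tuple[int, str | None, tuple[str, ...]] = (2**31, None, ())
    for _ in range(config.scramble_max_attempts):
        candidate = "".join(rng.permutation(chars))
        problems = [
            f"{h.match_type.value} site of {h.matched_id} at {h.start}"
            for h in scan_sequence(candidate, index).hits]
        for name, enzyme_site in config.flank_enzymes:
            if enzyme_site in candidate:
                problems.append(f"{name} site present")
        if not problems:
            return candidate
        if len(problems) < best[0]:
            best = (len(problems), candidate, tuple(problems))
    raise ScrambleSearchError(config.scramble_max_attempts, best[1], best[2])
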