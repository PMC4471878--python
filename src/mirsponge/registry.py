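"""Mature-miRNA registries: parsing, seed k-mers, orientation utilities.

A registry holds mature miRNA sequences (RNA, 5'->3') keyed by their
miRBase-style identifier (e.g. ``dme-miR-8-3p``). miRNA positions are
numbered 1-based from the 5' end throughout the package; the *seed* is
positions 2-7 and the *extended seed* positions 2-8. Family grouping is
by identical extended seed, the determinant of shared targeting.

All cross-module sequence comparison happens in DNA space: constructs
are DNA, miRNAs are stored as RNA and converted on demand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import AlphabetError, DuplicateIdError, FastaParseError

__all__ = [
    "MatchType",
    "DEFAULT_MATCH_TYPES",
    "ALL_MATCH_TYPES",
    "MatureMiRNA",
    "Registry",
    "parse_mirna_fasta",
    "write_mirna_fasta",
    "reverse_complement",
    "seed_kmers",
]


class MatchType(enum.Enum):
    """Canonical seed-match site types on the transcript sense strand.

    A transcript k-mer is a site of the given type when it equals the
    reverse complement of the stated miRNA positions, optionally with an
    adenosine opposite miRNA position 1:

    - ``6mer``: rc(m[2..7])
    - ``7mer-m8``: rc(m[2..8])
    - ``7mer-A1``: rc(m[2..7]) + A
    - ``8mer``: rc(m[2..8]) + A
    """

    MER6 = "6mer"
    MER7_A1 = "7mer-A1"
    MER7_M8 = "7mer-m8"
    MER8 = "8mer"

    @property
    def width(self) -> int:
        return _MATCH_WIDTHS[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_MATCH_WIDTHS = {
    MatchType.MER6: 6,
    MatchType.MER7_A1: 7,
    MatchType.MER7_M8: 7,
    MatchType.MER8: 8,
}

#: Default site types used for off-target screening: the 7-8 nt windows.
DEFAULT_MATCH_TYPES = frozenset(
    {MatchType.MER7_A1, MatchType.MER7_M8, MatchType.MER8})
ALL_MATCH_TYPES = frozenset(MatchType)

_RNA_ALPHABET = frozenset("ACGU")
_DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT_DNA = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def reverse_complement(seq: str, out_alphabet: str = "DNA") -> str:
    """Antiparallel Watson-Crick complement, written 5'->3'.

    Accepts any mix of DNA/RNA letters (T and U both complement to A)
    and emits the requested alphabet. ``reverse_complement`` is an
    involution within one alphabet.
    """
    if out_alphabet not in ("DNA", "RNA"):
        raise ValueError(f"out_alphabet must be 'DNA' or 'RNA', "
                         f"got {out_alphabet!r}")
    out = []
    for i, base in enumerate(seq):
        comp = _COMPLEMENT_DNA.get(base.upper())
        if comp is None:
            raise AlphabetError(
                f"illegal nucleotide {base!r} at offset {i}", offset=i)
        out.append(comp)
    rc = "".join(reversed(out))
    return rc.replace("T", "U") if out_alphabet == "RNA" else rc


def _validate_rna(seq: str, record_id: str | None = None) -> str:
    """Uppercase, convert T->U, and reject anything outside {A,C,G,U}."""
    seq = seq.upper().replace("T", "U")
    for i, base in enumerate(seq):
        if base not in _RNA_ALPHABET:
            where = f" in record {record_id!r}" if record_id else ""
            raise AlphabetError(
                f"illegal nucleotide {base!r} at offset {i}{where}",
                offset=i, record_id=record_id)
    return seq


@dataclass(frozen=True)
class MatureMiRNA:
    """One registry entry: identifier plus mature RNA sequence, 5'->3'.

    The constructor normalises to uppercase RNA (T converted to U) and
    rejects non-nucleotide characters. Length bounds are enforced at
    parse time, not here, so short synthetic miRNAs can be built
    directly in tests and worked examples.
    """

    id: str
    sequence: str
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("miRNA id must be non-empty")
        if not self.sequence:
            raise AlphabetError("miRNA sequence must be non-empty",
                                record_id=self.id)
        object.__setattr__(self, "sequence",
                           _validate_rna(self.sequence, self.id))

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def seed(self) -> str:
        """Extended seed, miRNA positions 2-8 (RNA); requires length >= 8."""
        if self.length < 8:
            raise ValueError(
                f"{self.id}: length {self.length} < 8, no extended seed")
        return self.sequence[1:8]


class Registry:
    """Ordered, id-unique collection of mature miRNAs.

    Family grouping (identical extended seed, positions 2-8) is derived
    on demand from the entries and never stored independently.
    """

    def __init__(self, entries: Iterable[MatureMiRNA] = ()):
        self._entries: list[MatureMiRNA] = []
        self._by_id: dict[str, MatureMiRNA] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: MatureMiRNA) -> None:
        if entry.id in self._by_id:
            raise DuplicateIdError(entry.id)
        self._entries.append(entry)
        self._by_id[entry.id] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[MatureMiRNA]:
        return iter(self._entries)

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self._by_id

    def __getitem__(self, mirna_id: str) -> MatureMiRNA:
        try:
            return self._by_id[mirna_id]
        except KeyError:
            raise KeyError(f"miRNA {mirna_id!r} not in registry") from None

    def get(self, mirna_id: str) -> MatureMiRNA | None:
        return self._by_id.get(mirna_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self._entries)

    @property
    def families(self) -> Mapping[str, frozenset[str]]:
        """Extended-seed k-mer (RNA) -> ids sharing it; a partition."""
        groups: dict[str, set[str]] = {}
        for m in self._entries:
            # entries too short for a seed form singleton pseudo-families
            key = m.seed if m.length >= 8 else f"<short:{m.id}>"
            groups.setdefault(key, set()).add(m.id)
        return {k: frozenset(v) for k, v in groups.items()}

    def family_of(self, mirna: MatureMiRNA | str) -> frozenset[str]:
        """Ids sharing the extended seed with ``mirna``.

        ``mirna`` may be an id in the registry or a standalone entry;
        for standalone entries the family is computed against the
        registry's seeds and always includes the query id itself.
        """
        m = self[mirna] if isinstance(mirna, str) else mirna
        if m.length < 8:
            return frozenset({m.id})
        members = {e.id for e in self._entries
                   if e.length >= 8 and e.seed == m.seed}
        members.add(m.id)
        return frozenset(members)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Registry):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Registry({len(self)} miRNAs)"


def parse_mirna_fasta(path: str | PathLike,
                      species_prefix: str | None = None,
                      length_bounds: tuple[int, int] = (18, 30)) -> Registry:
    """Read a miRBase-dialect mature FASTA into a :class:`Registry`.

    Ids are the first whitespace-delimited header token; the second
    token, when present, is kept as the accession (miRBase MIMAT
    numbers). T is accepted and converted to U. With ``species_prefix``
    (e.g. ``"dme"``) only ids beginning ``<prefix>-`` are retained; file
    order is preserved.

    Raises on duplicate ids, illegal characters (with record id and
    offset), sequences outside ``length_bounds``, and an empty registry
    after filtering.
    """
    lo, hi = length_bounds
    registry = Registry()
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        tokens = record.description.split()
        if not tokens:
            raise FastaParseError(f"record {n_records} has an empty header")
        mirna_id = tokens[0]
        if species_prefix is not None and \
                not mirna_id.startswith(species_prefix + "-"):
            continue
        accession = tokens[1] if len(tokens) > 1 else None
        seq = _validate_rna(str(record.seq), mirna_id)
        if not lo <= len(seq) <= hi:
            raise FastaParseError(
                f"record {mirna_id!r}: length {len(seq)} outside "
                f"[{lo}, {hi}]")
        registry.add(MatureMiRNA(mirna_id, seq, accession))
    if len(registry) == 0:
        detail = (f"no ids matching prefix {species_prefix!r}"
                  if species_prefix and n_records else "no records")
        raise FastaParseError(f"empty registry after parsing: {detail}")
    return registry


def write_mirna_fasta(registry: Registry, path: str | PathLike) -> None:
    """Write a registry back to mature-FASTA (RNA alphabet).

    Round-trips exactly with :func:`parse_mirna_fasta`: ids, accessions
    and sequences are preserved.
    """
    records = []
    for m in registry:
        records.append(SeqRecord(Seq(m.sequence), id=m.id,
                                 description=m.accession or ""))
    SeqIO.write(records, str(path), "fasta")


def seed_kmers(m: MatureMiRNA,
               match_types: Iterable[MatchType] = DEFAULT_MATCH_TYPES,
               ) -> dict[MatchType, str]:
    """DNA k-mers a transcript must contain to be a site of each type.

    The k-mer is read 5'->3' on the transcript sense strand; see
    :class:`MatchType` for the definitions. Requires miRNA length >= 9.
    """
    if m.length < 9:
        raise ValueError(
            f"{m.id}: length {m.length} < 9, seed k-mers undefined")
    rc_2_7 = reverse_complement(m.sequence[1:7], "DNA")
    rc_2_8 = reverse_complement(m.sequence[1:8], "DNA")
    table = {
        MatchType.MER6: rc_2_7,
        MatchType.MER7_M8: rc_2_8,
        MatchType.MER7_A1: rc_2_7 + "A",
        MatchType.MER8: rc_2_8 + "A",
    }
    return {t: table[t] for t in match_types}
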