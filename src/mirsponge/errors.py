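"""Exception hierarchy shared across the package."""


class MirspongeError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(MirspongeError, ValueError):
    """A sequence contains a character outside the expected alphabet.

    Carries the 0-based ``offset`` of the first illegal character and,
    where known, the ``record_id`` it came from.
    """

    def __init__(self, message: str, *, offset: int | None = None,
                 record_id: str | None = None):
        super().__init__(message)
        self.offset = offset
        self.record_id = record_id


class FastaParseError(MirspongeError):
    """A miRNA FASTA file could not be parsed into a valid registry."""


class DuplicateIdError(FastaParseError):
    """Two registry entries share the same identifier."""

    def __init__(self, mirna_id: str):
        super().__init__(f"duplicate miRNA id in registry: {mirna_id!r}")
        self.mirna_id = mirna_id


class DesignError(MirspongeError):
    """A sponge construct could not be designed from the given inputs."""


class LinkerExhaustionError(DesignError):
    """Every candidate linker was rejected by the junction screen.

    ``rejections`` maps each candidate to one blocking collision.
    """

    def __init__(self, rejections: dict[str, str]):
        lines = ", ".join(f"{cand}: {why}" for cand, why in
                          list(rejections.items())[:8])
        more = "" if len(rejections) <= 8 else f" (+{len(rejections) - 8} more)"
        super().__init__(
            f"all {len(rejections)} linker candidates rejected: {lines}{more}")
        self.rejections = rejections


class ScrambleSearchError(DesignError):
    """No collision-free permutation of the template was found.

    ``best_candidate`` is the permutation with the fewest residual
    collisions seen during the search; ``residual_collisions`` describes
    what still blocks it.
    """

    def __init__(self, attempts: int, best_candidate: str | None,
                 residual_collisions: tuple[str, ...]):
        super().__init__(
            f"no collision-free permutation found in {attempts} attempts; "
            f"best candidate {best_candidate!r} still blocked by: "
            + "; ".join(residual_collisions[:5]))
        self.attempts = attempts
        self.best_candidate = best_candidate
        self.residual_collisions = residual_collisions


class ScreenInputError(MirspongeError, ValueError):
    """A screen table violates a precondition (counts, replicates, labels)."""
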