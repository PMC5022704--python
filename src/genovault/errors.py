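"""Exception hierarchy.

Every error raised by the package derives from :class:`GenovaultError` so
callers (and the CLI) can catch the whole family with one clause.
"""


class GenovaultError(Exception):
    """Base class for all package errors."""


class AlphabetError(GenovaultError, ValueError):
    """A sequence contains a character outside the allowed alphabet."""

    def __init__(self, char: str, position: int, context: str = ""):
        self.char = char
        self.position = position
        msg = f"invalid character {char!r} at position {position}"
        if context:
            msg += f" in {context}"
        super().__init__(msg)


class FormatError(GenovaultError, ValueError):
    """Malformed input in a structured text format (FASTA/GTF/VCF/...)."""


class CoordinateError(GenovaultError, ValueError):
    """A genomic coordinate is out of range or an interval is inverted."""


class IntervalError(CoordinateError):
    """An interval fails start < end or has negative coordinates."""


class ManifestError(GenovaultError, ValueError):
    """A datawrap manifest.ini is missing or malformed."""


class DatawrapImportError(GenovaultError):
    """A datawrap could not be imported into the store."""


class NotFoundError(GenovaultError, KeyError):
    """A record, genome, set, or bundled datawrap name does not exist."""


class SchemaError(GenovaultError, ValueError):
    """An unknown record kind was named."""


class FieldError(GenovaultError, AttributeError):
    """An unknown field was named for a record kind."""


class ConflictError(GenovaultError):
    """Two retained allele decisions edit overlapping spans."""

    def __init__(self, loci, context: str = ""):
        self.loci = list(loci)
        msg = f"conflicting allele decisions at loci {self.loci}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class ConsistencyError(GenovaultError):
    """A variant's recorded reference allele disagrees with the genome."""

    def __init__(self, position: int, expected: str, found: str, context: str = ""):
        self.position = position
        self.expected = expected
        self.found = found
        msg = (
            f"reference allele mismatch at position {position}: "
            f"expected {expected!r}, found {found!r}"
        )
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class FixtureSpecError(GenovaultError, ValueError):
    """A synthetic-datawrap specification is infeasible or invalid."""
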