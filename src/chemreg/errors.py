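"""Exception hierarchy.

Everything raised by chemreg derives from :class:`ChemregError` so callers
can catch domain failures without masking programming errors.
"""


class ChemregError(Exception):
    """Base class for all chemreg errors."""


class ParseError(ChemregError):
    """Input text is not valid SMILES / SMARTS / molfile / formula.

    Carries optional ``position`` (character offset when known) and
    ``reason`` attributes.
    """

    def __init__(self, message: str, *, position: int | None = None,
                 reason: str | None = None):
        super().__init__(message)
        self.position = position
        self.reason = reason


class ValenceError(ParseError):
    """Chemically impossible atom (valence violation) in otherwise
    syntactically valid input."""


class UnknownElementError(ChemregError):
    """Element symbol outside the periodic table."""


class KeyGenerationError(ChemregError):
    """Neither the InChIKey nor the fallback digest could be produced."""


class ParamsMismatchError(ChemregError):
    """Two fingerprints generated with different parameters were compared."""


class FormatError(ChemregError):
    """Malformed SD-file record. Carries the 0-based record index."""

    def __init__(self, message: str, *, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class StoreError(ChemregError):
    """Store target unusable (unwritable path, corrupt file, ...)."""


class ConstraintError(ChemregError):
    """A database-level constraint (unique key, not-null, check) failed."""


class UniquenessError(ChemregError):
    """A uniqueness policy rejected the entity as a duplicate."""


class ConcurrentModificationError(ChemregError):
    """Optimistic-lock version mismatch on update."""


class NotFoundError(ChemregError):
    """Referenced entity does not exist."""


class UnknownFieldError(ChemregError):
    """A search filter or sort references a field the target type lacks."""


class AuthorizationError(ChemregError):
    """A write guard denied the operation."""


class AbortError(ChemregError):
    """Bulk import aborted on first failure (policy 'abort')."""

    def __init__(self, message: str, *, record_index: int | None = None,
                 report=None):
        super().__init__(message)
        self.record_index = record_index
        self.report = report


class IOError_(ChemregError):
    """Stream read/write failure during SD-file I/O."""
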