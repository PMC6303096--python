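"""Exception hierarchy for barcodeaudit."""


class BarcodeAuditError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(BarcodeAuditError):
    """An input file or collection was empty."""


class AlignmentLengthError(BarcodeAuditError):
    """Sequences do not share the library alignment length.

    ``offending_ids`` lists the records whose length disagrees with the
    majority/first length seen.
    """

    def __init__(self, message: str, offending_ids=()):
        super().__init__(message)
        self.offending_ids = list(offending_ids)


class MetadataJoinError(BarcodeAuditError):
    """FASTA ids missing from the metadata table."""

    def __init__(self, message: str, missing_ids=()):
        super().__init__(message)
        self.missing_ids = list(missing_ids)


class NewickParseError(BarcodeAuditError):
    """Malformed newick input; ``offset`` is a character offset when known."""

    def __init__(self, message: str, offset=None):
        super().__init__(message)
        self.offset = offset


class UndefinedDistanceError(BarcodeAuditError):
    """An operation required defined distances but some pairs are undefined."""

    def __init__(self, message: str, pairs=()):
        super().__init__(message)
        self.pairs = list(pairs)


class InsufficientOverlapError(BarcodeAuditError):
    """Strict mode: a pair fell below the minimum comparable-site count."""

    def __init__(self, message: str, pairs=()):
        super().__init__(message)
        self.pairs = list(pairs)


class TreeLibraryMismatchError(BarcodeAuditError):
    """Tree leaf set and library specimen ids disagree."""


class BootstrapError(BarcodeAuditError):
    """Too many bootstrap replicates were discarded."""
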