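"""Typed exceptions shared across the package."""


class CrmkitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CrmkitError):
    """Malformed on-disk input (FASTA, BED, matrix text, tables)."""


class DuplicateIdError(FormatError):
    """Two records in one file share an identifier."""


class AlphabetError(FormatError):
    """A sequence contains characters outside the accepted alphabet."""


class DegenerateColumnError(CrmkitError):
    """A count-matrix column has zero total and no pseudocount to rescue it."""


class CoordinateError(CrmkitError):
    """An interval or hit lies outside its sequence."""
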