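"""Shared exception types."""


class LdrefineError(Exception):
    """Base class for package errors."""


class ValidationError(LdrefineError):
    """A configuration or argument violates its invariants."""


class FormatError(LdrefineError):
    """An input file does not conform to its declared format."""


class ConsistencyError(LdrefineError):
    """Two inputs that must agree (e.g. VCF vs FASTA) do not."""


class UndefinedLDError(LdrefineError):
    """LD is undefined for a site or block pair (monomorphic / no data)."""
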