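"""Exception types shared across the package."""


class IcrScanError(Exception):
    """Base class for all package errors."""


class AlphabetError(IcrScanError):
    """A sequence contains characters outside the allowed DNA alphabet."""


class FormatError(IcrScanError):
    """A file violates its format contract.

    Where possible the message names the offending line number.
    """


class SpecError(IcrScanError):
    """A synthetic-genome or parameter specification is inconsistent."""
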