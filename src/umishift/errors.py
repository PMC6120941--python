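"""Exception hierarchy.

Exit-code mapping used by the CLI: usage errors (2) are raised by click
itself; :class:`FormatError` and :class:`ConfigError` exit with 3; anything
else is an internal error (1).
"""


class UmishiftError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(UmishiftError):
    """Malformed input record (FASTQ, SAM, GFF3...). Names the offending record."""


class PairingError(FormatError):
    """Mate-pair records whose read identifiers do not match."""


class ConfigError(UmishiftError):
    """Inconsistent or incomplete run configuration."""
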