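"""Exception hierarchy for beatkit.

Readers reject rather than repair invalid input; every failure mode the
pipeline can hit maps to one of these so callers (and the CLI) can react
without string-matching messages.
"""


class BeatkitError(Exception):
    """Base class for all beatkit errors."""


class ConfigurationError(BeatkitError, ValueError):
    """Invalid simulation or analysis configuration."""


class MetadataError(BeatkitError):
    """Required physical metadata (frame rate, pixel width) missing."""


class FormatError(BeatkitError):
    """File exists but cannot be parsed as the expected format."""


class ValidationError(BeatkitError, ValueError):
    """Input object violates a documented invariant."""


class GeometryError(BeatkitError):
    """A geometric operation is impossible on the given traces."""


class NoPeriodicityError(BeatkitError):
    """No cardiac period detectable in the signal."""


class InsufficientCyclesError(BeatkitError):
    """Fewer complete beating cycles than requested."""
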