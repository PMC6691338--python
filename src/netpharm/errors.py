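"""Exception hierarchy.

Every error raised by the library derives from :class:`NetpharmError`, so
callers (and the CLI) can catch one type at the pipeline boundary.
"""


class NetpharmError(Exception):
    """Base class for all netpharm errors."""


class FormatError(NetpharmError):
    """A file or table does not conform to the expected layout."""


class ParseError(NetpharmError):
    """A cell could not be parsed (carries the offending row where known)."""


class ConfigurationError(NetpharmError):
    """Inputs are individually valid but jointly unusable."""


class CapabilityError(NetpharmError):
    """A requested operation is not available for this input or provider."""


class ParameterError(NetpharmError):
    """A numeric or structural parameter is out of its admissible range."""
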