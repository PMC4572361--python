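"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`FmctError`,
so callers can catch one type at CLI boundaries.
"""


class FmctError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(FmctError):
    """Bad build/query configuration: unknown fingerprint family, missing
    TSV column, invalid dialect entry, ..."""


class StructureError(FmctError):
    """A SMILES/SDF input failed to parse or sanitize."""


class ComparabilityError(FmctError):
    """Two fingerprints cannot be compared (family or length mismatch)."""


class FormatError(FmctError):
    """A persisted table or selection file is corrupt or has an
    unsupported format version."""


class TransportError(FmctError):
    """HTTP transport failure after retries."""


class ServiceParseError(FmctError):
    """The web-service returned XML we cannot interpret."""


class InputError(FmctError):
    """User-supplied batch input is unusable (e.g. every query unparsable)."""
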