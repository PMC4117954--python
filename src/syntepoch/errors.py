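"""Exception hierarchy shared across the package."""


class SyntepochError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SyntepochError):
    """A file could not be parsed (malformed line, bad record)."""


class SchemaError(SyntepochError):
    """A tabular input is missing required columns."""


class ValidationError(SyntepochError):
    """Parsed content violates a domain invariant."""


class ConfigError(SyntepochError):
    """A configuration value is impossible or inconsistent."""


class SequenceError(SyntepochError):
    """A CDS is untranslatable (internal stop, bad length, empty)."""
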