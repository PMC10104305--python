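"""Exception taxonomy shared across the pipeline.

The CLI maps these onto exit codes (schema -> 2, invariant -> 3); library
users catch them directly.
"""


class RaphiaError(Exception):
    """Base class for all package errors."""


class SchemaError(RaphiaError):
    """A table is structurally wrong: missing column, unknown label, bad header."""


class ParseError(SchemaError):
    """A cell could not be parsed as the declared type (row context included)."""


class InvariantError(RaphiaError):
    """A record violates a domain invariant (e.g. component masses not summing)."""


class DomainError(RaphiaError, ValueError):
    """A scalar argument is outside its mathematical domain."""


class IntegrityError(RaphiaError):
    """The packaged coefficient fixture does not match its recorded checksum."""


class ModelNotFoundError(RaphiaError, KeyError):
    """Requested allometric model id is not in the fixture or fitted table."""


class ConfigError(RaphiaError):
    """A simulation or pipeline configuration is internally inconsistent."""
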