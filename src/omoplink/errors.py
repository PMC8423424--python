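"""Exception hierarchy shared across the pipeline.

The CLI maps these onto fixed exit codes: missing inputs -> 2,
schema problems -> 3, integrity/invariant violations -> 4.
"""


class OmoplinkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OmoplinkError):
    """Invalid run or generator configuration; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class SchemaError(OmoplinkError):
    """A table does not match its declared schema (missing column, bad type)."""


class IntegrityError(OmoplinkError):
    """A structural invariant is violated (duplicate ids, dangling references)."""


class VocabularyLookupError(OmoplinkError):
    """An unknown vocabulary, phenotype or concept was requested."""
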