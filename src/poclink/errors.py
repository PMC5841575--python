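"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`IntegrityError` -> 3, anything else -> 1.
"""


class PoclinkError(Exception):
    """Base class for all package errors."""


class InputError(PoclinkError):
    """Malformed or unusable user input (bad CSV schema, bad ID format,
    unsearchable query, bad parameter values)."""


class IntegrityError(PoclinkError):
    """Data that violates an internal consistency contract (duplicate
    record IDs, dangling references, key collisions)."""


class SchemaError(InputError):
    """A CSV file is missing required columns or has an unknown layout."""


class UnsearchableQueryError(InputError):
    """The query cannot be run (no names, or the reported residence is
    outside the surveillance area)."""


class ParameterError(InputError):
    """A match parameter is out of its valid range."""


class IdFormatError(InputError):
    """A clinic identifier contains characters its scheme forbids
    (distinct from a failed check-digit test, which is a boolean result)."""


class EstimationError(PoclinkError):
    """A u-probability cannot be estimated (degenerate field)."""


class LookupError_(PoclinkError):
    """A referenced key does not exist in the store or registry."""


class SessionError(PoclinkError):
    """Session bookkeeping failure (record-number overflow, key collision)."""
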